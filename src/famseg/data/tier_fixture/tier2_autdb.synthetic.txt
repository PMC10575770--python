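# Synthetic stand-in for the Tier-2 evidence sources (AutDB and companions);
# fixture genes only.
JADE2
ESR1
MAP2
SEMA3F
TAF4
CLOCK
JAG1
NCOR2
STXBP5L
TNS3
TTC28
PHLPP1
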