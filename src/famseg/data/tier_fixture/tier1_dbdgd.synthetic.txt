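# Synthetic stand-in for the Developmental Brain Disorder Gene Database;
# fixture genes only.
YTHDC1
KDM3A
PTCH1
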