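# Synthetic stand-in for the Tier-3 brain/synaptome gene sets; fixture genes only.
CASKIN1
FAT3
PCDH1
VCAN
PCLO
TP53BP1
DGKI
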