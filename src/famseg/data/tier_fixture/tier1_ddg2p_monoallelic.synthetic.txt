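# Synthetic stand-in for the DDG2P monoallelic (confirmed/probable/possible)
# developmental-disorder gene list; fixture genes only.
KMT2C
ANKRD11
SETD2
CUX1
MTOR
BRPF1
CHD7
SON
RIMS2
KDM5A
DYNC1H1
ZBTB18
WDR7
MACF1
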