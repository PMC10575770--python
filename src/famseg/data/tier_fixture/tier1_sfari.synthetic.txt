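# Synthetic stand-in for the SFARI Gene list (categories S, 1-3).
# Contains only the fixture genes needed for the package's worked examples;
# supply a full snapshot via the tier-sources config for real analyses.
ATP2B2
PREX1
PTPRT
PSMD1
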