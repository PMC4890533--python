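# Predicted miRNA -> target links for the four published pairs (aggregated
# from three target-prediction algorithms; per-link source detail was not
# published, so provenance is recorded as "predicted").
mirna	gene	sources
miR-33-5p	Gyk	predicted
miR-221-3p	Serpinb1a	predicted
miR-200c-5p	Rpsa	predicted
miR-212-3p	Actb	predicted
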