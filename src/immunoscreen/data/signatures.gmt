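immune	synthetic stand-in for an ESTIMATE-style immune signature	CD2	CD3D	CD3E	CD48	CD52	CCL5	CXCL9	GZMB	IL7R	LCK	LTB	PTPRC	SELL	TRAC	TRBC1	IGHM	CD27	CCR7	SLAMF1	KLRB1
CYT	cytolytic activity genes	GZMA	PRF1
MHC	antigen presentation machinery	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2	NLRC5	PSMB8	PSMB9
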