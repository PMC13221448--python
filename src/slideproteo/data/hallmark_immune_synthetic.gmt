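IFNG_RESPONSE_SYNTHETIC	small curated stand-in for the hallmark interferon-gamma response set; supply the MSigDB hallmark GMT for real analyses	STAT1	STAT2	IRF1	IRF7	GBP2	GBP4	TAP1	TAP2	PSMB8	PSMB9	PSMB10	B2M	HLA-A	HLA-B	HLA-E	HLA-DQA1	HLA-DRB1	CXCL9	CXCL10	CXCL11	IDO1	OAS1	OAS2	OAS3	MX1	MX2	ISG15	IFIT1	IFIT3	BST2	IL15	SOCS1
INFLAMMATORY_RESPONSE_SYNTHETIC	small curated stand-in for the hallmark inflammatory response set; supply the MSigDB hallmark GMT for real analyses	IL1B	IL6	TNF	CXCL8	CCL2	CCL5	TLR2	TLR4	NFKB1	RELA	PTGS2	ICAM1	VCAM1	SELE	C3	C5AR1	CD14	ITGAM	FPR1	NLRP3	IL18	CD40	CD69	CCR1	CCR5	OSM	LIF	IL10RA	IL4R	PDE4B
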