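IMMUNE_CELL_MARKERS_SYNTHETIC	small curated stand-in for the published 782-gene immune cell-type marker compendium; supply the full list via --signatures for real analyses	PTPRC	CD3D	CD3E	CD3G	CD2	CD4	CD8A	CD8B	CD19	MS4A1	CD79A	CD79B	CD14	CD68	CD163	FCGR3A	ITGAM	ITGAX	NCAM1	KLRD1	KLRB1	NKG7	GZMA	GZMB	GZMK	PRF1	IL2RB	IL2RA	CCR7	SELL	LCK	ZAP70	SYK	BTK	FOXP3	CTLA4	TNFRSF9	HAVCR2	LAG3	CD27	CD28	CD1C	CLEC4C	TLR7	CD40LG
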