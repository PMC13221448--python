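AC_MARKERS	default lung adenocarcinoma marker panel (editorial, overridable)	NKX2-1	NAPSA
SCC_MARKERS	default lung squamous cell carcinoma marker panel (editorial, overridable)	TP63	KRT5	KRT6A	DSG3
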