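SKIN_KERATINS	skin/hair keratin contaminant panel (overridable)	KRT1	KRT2	KRT5	KRT6A	KRT9	KRT10	KRT14	KRT16	KRT17
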