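LUNG_ACTIONABLE_MARKERS_SYNTHETIC	small curated stand-in for a clinically actionable lung-cancer marker list; supply a current database export for real analyses	EGFR	ALK	ROS1	BRAF	MET	ERBB2	KRAS	RET	NTRK1	NTRK2	NTRK3	CD274	MAP2K1	PIK3CA	STK11	KEAP1	RBM10	TP53
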