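EMT_POSITIVE	positive EMT regulators and markers	AHNAK	BMP1	CALD1	CAMK2N1	CDH2	COL1A2	COL3A1	COL5A2	FN1	FOXC2	GNG11	GSC	IGFBP4	ITGA5	ITGAV	MMP2	MMP3	MMP9	MSN	SERPINE1	SNAI1	SNAI2	SNAI3	SOX10	SPARC	STEAP1	TCF4	TIMP1	TMEFF1	TMEM132A	TWIST1	VCAN	VIM	VPS13A	WNT5A	WNT5B
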