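POU5F1	reg	FRAT2
FRAT2	ppi	GSK3B
GSK3B	ppi	MYCN
KLF4	ppi	CREBBP
CREBBP	ppi	GLI3
GLI3	ppi	ZIC3
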