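node	role
POU5F1	source
KLF4	source
MYCN	sink
ZIC3	sink
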