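name	vgt1	id1	dlf1	zmm4_transgene
B73	0	1	1	0
id1 mutant	0	0	1	0
dlf1 mutant	0	1	0	0
Gaspe Flint	1	1	1	0
id1 dlf1	0	0	0	0
ZMM4 B73	0	1	1	1
ZMM4 id1 mutant	0	1	0	1
ZMM4 dlf1 mutant	0	0	1	1
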