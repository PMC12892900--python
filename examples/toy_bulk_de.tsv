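gene	log2fc	p	fdr
g1	3.0	0.0005	0.001
g2	2.0	0.0005	0.001
g3	-1.0	0.00005	0.0001
g4	2.0	0.1	0.2
g5	-2.0	0.0005	0.001
g6	1.0	0.0005	0.001
g7	-1.0	0.0005	0.001
g8	1.0	0.0005	0.001
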