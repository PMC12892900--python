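gene	log2fc	p	fdr
g1	2.5	1e-10	1e-09
g2	3.0	1e-09	1e-08
g3	-2.2	1e-10	1e-09
g4	4.0	1e-10	1e-09
g5	2.6	1e-10	1e-09
g6	1.5	1e-10	1e-09
g7	-3.0	1e-07	1e-06
g8	2.5	1e-08	1e-07
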