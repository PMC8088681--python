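chromosome	gene	ratio_map	ratio_qpcr
10	IFIT1	5.76	0.90
21	SLC19A1	3.50	2.02
21	TSPEAR	16.79	9.27
21	MX1	6.76	2.07
21	GART	1.58	2.80
12	GAPDH	1.21	1.00
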