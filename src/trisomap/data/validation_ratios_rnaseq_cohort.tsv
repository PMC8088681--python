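chromosome	gene	ratio_map	ratio_qpcr
15	B2M	1.31	1.29
5	DHFR	1.00	0.17
21	DYRK1A	1.65	1.01
21	ETS2	2.80	2.81
12	GAPDH	1.21	1.00
19	HCST	1.15	0.86
11	LRP5	0.66	0.60
21	MX1	6.76	6.96
9	NACC2	1.15	1.48
7	NDUFA4	1.41	1.06
17	NPTX1	0.25	0.13
11	NRGN	0.87	0.77
12	NUAK1	4.47	7.84
19	PRDX2	1.05	0.68
1	RYR2	1.13	0.37
17	SERPINF1	2.33	0.67
21	SOD1	1.41	1.33
12	TUBA1B	1.13	0.57
7	YKT6	1.16	1.15
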