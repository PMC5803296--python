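entrez	symbol	od_probe	od_ratio	od_adj_p	ppp_probe	ppp_ratio	ppp_adj_p
51239/200539	ANKRD23/39	229052_at	0.585	1.14e-2	1553366_s_at	0.600	1.80e-3
384	ARG2	203946_s_at	0.605	3.28e-4	203946_s_at	0.463	1.47e-9
430	ASCL2	229215_at	0.540	2.52e-3	229215_at	0.463	1.74e-8
92291	CAPN13	229499_at	0.535	2.52e-3	229499_at	0.614	4.66e-3
10752	CHL1	204591_at	0.411	1.61e-3	204591_at	0.446	1.56e-5
338557	FFAR4	240856_at	0.604	1.10e-2	240856_at	0.566	1.79e-3
57818	G6PC2	221453_at	0.616	3.43e-2	221453_at	0.643	2.77e-2
57467	HHATL	223572_at	0.388	1.09e-4	223572_at	0.415	4.44e-4
27065	NSG1	209569_x_at	0.624	2.41e-2	209569_x_at	0.610	8.59e-4
64881	PCDH20	232054_at	0.628	2.98e-2	232054_at	0.612	4.02e-2
5502	PPP1R1A	235129_at	0.419	3.07e-4	235129_at	0.475	5.54e-6
6344	SCTR	1565737_at	0.531	4.68e-4	1565737_at	0.495	8.30e-4
6514	SLC2A2	206535_at	0.273	1.65e-4	206535_at	0.362	1.74e-8
140738	TMEM37	1554485_s_at	0.654	3.90e-3	227190_at	0.504	3.84e-9
137970	UNC5D	231325_at	0.535	1.29e-2	231325_at	0.589	1.20e-2
960	CD44	217523_at	1.561	2.30e-2	1557905_s_at	1.681	1.84e-2
284611	FAM102B	226568_at	1.538	9.05e-3	226568_at	1.636	2.15e-2
114907	FBXO32	232729_at	1.716	1.51e-3	225328_at	1.505	7.66e-3
131096	KCNH8	1552742_at	1.529	1.09e-2	1552742_at	1.644	1.74e-2
1600	DAB1	228329_at	0.616	3.90e-2	228329_at	1.551	4.59e-2
2596	GAP43	204471_at	0.611	1.94e-2	204471_at	1.880	2.33e-2
5166	PDK4	1562321_at	0.537	8.37e-3	1562321_at	2.120	4.06e-2
6004	RGS16	209324_s_at	0.663	2.23e-2	209324_s_at	1.687	3.80e-2
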