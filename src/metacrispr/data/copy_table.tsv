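sample_id	individual	household	sample_type	site	dilution_factor	locus	copies_per_ul	bacterial_dna_pg_ul	human_dna_pg_ul
1	P03	H4	skin	Hp-L	1	CRISPR3	510.3	2.5	4.0
1	P03	H4	skin	Hp-L	1	CRISPR1	446.2	2.5	4.0
2	P03	H4	skin	Hp-R	1	CRISPR3	1829.3	4.2	1.9
2	P03	H4	skin	Hp-R	1	CRISPR1	1360.3	4.2	1.9
3	P06	H5	skin	Hp-L	1	CRISPR3	49.6*	1.4	5.4
3	P06	H5	skin	Hp-L	1	CRISPR1	6.5*	1.4	5.4
4	P06	H5	skin	Hp-R	1	CRISPR3	24.1*	0.4	4.4
4	P06	H5	skin	Hp-R	1	CRISPR1	ND	0.4	4.4
5	P01	H6	skin	Hp-L	1	CRISPR3	53.8*	55.9	131.3
5	P01	H6	skin	Hp-L	1	CRISPR1	989.8	55.9	131.3
6	P01	H6	skin	Hp-R	1	CRISPR3	184.8	9.7	38.5
6	P01	H6	skin	Hp-R	1	CRISPR1	2502.5	9.7	38.5
7	P04	H1	skin	Hp-L	1	CRISPR3	1060.0	7.8	5.3
7	P04	H1	skin	Hp-L	1	CRISPR1	5244.0	7.8	5.3
8	P04	H1	skin	Hp-R	1	CRISPR3	238.1	5.7	4.4
8	P04	H1	skin	Hp-R	1	CRISPR1	2254.7	5.7	4.4
9	P07	H1	skin	Hp-L	1	CRISPR3	118.9	18.4	41.1
9	P07	H1	skin	Hp-L	1	CRISPR1	12827.5	18.4	41.1
10	P07	H1	skin	Hp-R	1	CRISPR3	2387.8	58.8	934.3
10	P07	H1	skin	Hp-R	1	CRISPR1	12325.7	58.8	934.3
11	P08	H2	skin	Hp-L	1	CRISPR3	7.8*	5.0	52.5
11	P08	H2	skin	Hp-L	1	CRISPR1	1237.4	5.0	52.5
12	P08	H2	skin	Hp-R	1	CRISPR3	99.5*	4.9	38.0
12	P08	H2	skin	Hp-R	1	CRISPR1	810.2	4.9	38.0
13	P09	H2	skin	Hp-L	1	CRISPR3	27.1*	8.8	14.6
13	P09	H2	skin	Hp-L	1	CRISPR1	2466.6	8.8	14.6
14	P09	H2	skin	Hp-R	1	CRISPR3	52.5*	9.6	58.1
14	P09	H2	skin	Hp-R	1	CRISPR1	3079.9	9.6	58.1
15	P10	H7	skin	Hp-L	1	CRISPR3	470.4	4.9	37.7
15	P10	H7	skin	Hp-L	1	CRISPR1	386.2	4.9	37.7
16	P10	H7	skin	Hp-R	1	CRISPR3	140.9	4.9	92.6
16	P10	H7	skin	Hp-R	1	CRISPR1	495.0	4.9	92.6
17	P11	H3	skin	Hp-L	1	CRISPR3	43.8*	1.2	2.7
17	P11	H3	skin	Hp-L	1	CRISPR1	299.0	1.2	2.7
18	P11	H3	skin	Hp-R	1	CRISPR3	463.1	1.3	4.7
18	P11	H3	skin	Hp-R	1	CRISPR1	4667.0	1.3	4.7
19	P12	H3	skin	Hp-L	1	CRISPR3	25.9*	14.9	17.7
19	P12	H3	skin	Hp-L	1	CRISPR1	298.5	14.9	17.7
20	P12	H3	skin	Hp-R	1	CRISPR3	24.6*	6.9	8.8
20	P12	H3	skin	Hp-R	1	CRISPR1	633.9	6.9	8.8
21	P04	H1	skin	Hp-L	1	CRISPR3	108.9	78.1	201.9
21	P04	H1	skin	Hp-L	1	CRISPR1	33718.9	78.1	201.9
22	P04	H1	skin	Hp-R	1	CRISPR3	44.1*	35.5	66.7
22	P04	H1	skin	Hp-R	1	CRISPR1	17809.3	35.5	66.7
23	P03	H4	saliva	Saliva	1	CRISPR3	105085.8	1299.2	4315.2
23	P03	H4	saliva	Saliva	1	CRISPR1	178727.9	1299.2	4315.2
24	P06	H5	saliva	Saliva	1	CRISPR3	69332	2588.2	10435.4
24	P06	H5	saliva	Saliva	1	CRISPR1	188751.7	2588.2	10435.4
25	P01	H6	saliva	Saliva	1	CRISPR3	349187	23162.5	16369.3
25	P01	H6	saliva	Saliva	1	CRISPR1	1341240.9	23162.5	16369.3
26	P04	H1	saliva	Saliva	1	CRISPR3	874576.4	4792.5	17199.2
26	P04	H1	saliva	Saliva	1	CRISPR1	876025.1	4792.5	17199.2
27	P07	H1	saliva	Saliva	1	CRISPR3	11837.3	238.9	815.7
27	P07	H1	saliva	Saliva	1	CRISPR1	19063.5	238.9	815.7
28	P08	H2	saliva	Saliva	1	CRISPR3	2857.1	67.1	364.3
28	P08	H2	saliva	Saliva	1	CRISPR1	34498.1	67.1	364.3
29	P09	H2	saliva	Saliva	1	CRISPR3	4429.6	536.2	2801.6
29	P09	H2	saliva	Saliva	1	CRISPR1	83532.9	536.2	2801.6
33	P10	H7	saliva	Saliva	1	CRISPR3	19854.2	3995.6	2641.9
33	P10	H7	saliva	Saliva	1	CRISPR1	84035.5	3995.6	2641.9
34	P11	H3	saliva	Saliva	1	CRISPR3	32633.3	1769.4	2682.1
34	P11	H3	saliva	Saliva	1	CRISPR1	1344976.6	1769.4	2682.1
35	P12	H3	saliva	Saliva	1	CRISPR3	27743.4	1787.0	3426.4
35	P12	H3	saliva	Saliva	1	CRISPR1	339729.3	1787.0	3426.4
36	P04	H1	saliva	Saliva	1	CRISPR3	8977.3	2805.4	1409.6
36	P04	H1	saliva	Saliva	1	CRISPR1	509864.7	2805.4	1409.6
37	P09	H2	object	Object	1	CRISPR3	1539.6	0.8	28.4
37	P09	H2	object	Object	1	CRISPR1	1252.7	0.8	28.4
38	P10	H7	object	Object	1	CRISPR3	2502.5	0.4	21.8
38	P10	H7	object	Object	1	CRISPR1	5540.4	0.4	21.8
39	P12	H3	object	Object	1	CRISPR3	26.7*	0.3	5.0
39	P12	H3	object	Object	1	CRISPR1	5.3*	0.3	5.0
40	P04	H1	object	Object	1	CRISPR3	1463.1	0.8	28.4
40	P04	H1	object	Object	1	CRISPR1	1429.6	0.8	28.4
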