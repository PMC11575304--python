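sample_id	individual	site	bc_crispr3	bc_crispr1	correct_loci
1	P03	Hp-L	0.28	0.55	21
2	P03	Hp-R	0.19	0.51	12
3	P06	Hp-L	0.48	0.79	20
4	P06	Hp-R	0.86	1.00	17
5	P01	Hp-L	0.55	0.61	20
6	P01	Hp-R	0.45	0.54	13
7	P04	Hp-L	0.82	0.40	19
8	P04	Hp-R	0.67	0.55	18
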