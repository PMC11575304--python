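sample_id	individual	site	bc_crispr3	bc_crispr1	correct_loci
1	P03	Hp-L	1.00	0.67	0
2	P03	Hp-R	0.59	0.80	0
3	P06	Hp-L	1.00	1.00	0
4	P06	Hp-R	1.00	1.00	0
5	P01	Hp-L	1.00	1.00	19
6	P01	Hp-R	0.98	0.98	3
7	P04	Hp-L	1.00	0.96	0
8	P04	Hp-R	1.00	0.49	0
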