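toxin_class	n	nuc_model	m1_p0	m1_p1	m1_w0	m1_w1	m1_neglnl	m2_p0	m2_p1	m2_p2	m2_w0	m2_w1	m2_w2	m2_neglnl	m0_omega	lambda	p_value
3FTx	26	F81+G	0.27	0.73	0.11	1.00	1600.40	0.13	0.31	0.56	0.00	1.00	3.79	1576.50	1.48	47.8	4.17e-11
KUN	9	GTR+G	0.32	0.68	0.02	1.00	965.08	0.31	0.45	0.24	0.03	1.00	2.74	962.16	0.58	5.84	5.39e-2
LCN	9	JC+I	0.86	0.14	1.00	1.00	315.85	0.84	0.00	0.16	0.00	1.00	999.00	305.84	999.00	20.02	4.49e-5
PLA2	52	SYM+G	0.66	0.34	0.05	1.00	4761.33	0.49	0.28	0.23	0.04	1.00	11.68	4359.71	3.32	443.24	0.00
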