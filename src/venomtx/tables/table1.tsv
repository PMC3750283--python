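rank	cluster_name	cluster_size	length	pct_toxin_reads	pct_total_reads
1	PLA2-2	11	643	5.366	2.455
2	PLA2-5	2	826	5.294	2.422
3	PLA2-16	1	815	5.036	2.304
4	3FTx-2	6	616	4.803	2.197
5	PLA2-1	4	809	4.195	1.919
6	PLA2-17	1	681	3.541	1.620
7	3FTx-1	4	394	3.424	1.567
8	3FTx-3	2	532	3.327	1.522
9	PLA2-11	1	1534	3.162	1.447
10	PLA2-12	1	776	3.031	1.387
11	SVMP-1	1	2323	2.947	1.348
12	PLA2-4	6	702	2.924	1.338
13	PLA2-26	1	638	2.856	1.307
14	PLA2-24	1	760	2.835	1.297
15	PLA2-14	1	1074	2.801	1.281
16	3FTx-4	2	568	2.617	1.197
17	PLA2-3	2	874	2.278	1.042
18	PLA2-8	1	1846	2.001	0.915
19	PLA2-29	1	487	1.913	0.875
20	3FTx-6	1	382	1.873	0.857
21	PLA2-6	3	681	1.860	0.851
22	PLA2-20	1	825	1.518	0.695
23	PLA2-23	1	876	1.425	0.652
24	PLA2-7	2	782	1.411	0.645
25	PLA2-27	1	550	1.361	0.623
26	PLA2-28	1	565	1.333	0.610
27	PLA2-13	1	754	1.302	0.596
28	PLA2-30	1	730	1.182	0.541
29	3FTx-7	1	603	1.145	0.524
30	PLA2-9	1	631	1.097	0.502
31	PLA2-22	1	666	1.006	0.460
32	3FTx-9	1	593	0.992	0.454
33	LCN-4	1	471	0.985	0.451
34	PLA2-25	1	515	0.897	0.410
35	LAAO-1	3	2359	0.880	0.403
36	PLA2-19	1	985	0.798	0.365
37	LCN-1	3	613	0.795	0.364
38	CTL-1	2	939	0.790	0.361
39	3FTx-11	1	496	0.784	0.359
40	KUN-2	1	551	0.782	0.358
41	PLA2-15	1	620	0.754	0.345
42	PLA2-31	1	506	0.720	0.330
43	NP-1	1	642	0.701	0.321
44	LCN-3	1	591	0.673	0.309
45	VEGF-1	1	4642	0.629	0.288
46	KUN-1	2	421	0.600	0.274
47	NGF-1	2	1014	0.576	0.264
48	PLA2-18	1	651	0.576	0.263
49	3FTx-14	1	377	0.522	0.239
50	LCN-6	1	548	0.504	0.231
51	3FTx-12	1	605	0.448	0.205
52	3FTx-13	1	492	0.439	0.201
53	LCN-2	1	734	0.390	0.179
54	3FTx-10	1	417	0.371	0.170
55	LCN-5	1	487	0.345	0.158
56	LCN-7	1	371	0.339	0.155
57	PLB-1	1	1790	0.337	0.154
58	PLA2-21	1	668	0.325	0.149
59	KUN-7	1	442	0.303	0.139
60	KUN-3	1	442	0.284	0.130
61	VEGF-2	1	1260	0.248	0.113
62	NUC-1	1	2297	0.226	0.103
63	3FTx-15	1	625	0.202	0.092
64	HYAL-1	1	1448	0.195	0.089
65	VEGF-3	1	1422	0.171	0.078
66	3FTx-8	1	707	0.131	0.060
67	PDE-1	1	3003	0.114	0.052
68	KUN-8	1	571	0.072	0.033
69	KUN-5	1	400	0.063	0.029
70	PLA2-10	1	1120	0.055	0.025
71	3FTx-5	2	1680	0.051	0.023
72	KUN-6	1	304	0.026	0.012
73	KUN-4	1	856	0.024	0.011
74	CREGF-1	1	1573	0.014	0.007
75	CTL-2	1	1020	0.009	0.004
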