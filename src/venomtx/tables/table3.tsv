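transcript	type	coverage	position	snp_pct	aa_ref	aa_alt	effect
40S ribosomal protein S14	Nontoxin	762	292	52.0	D	D	synonymous
40S ribosomal protein S18	Nontoxin	284	424	47.2	N	N	synonymous
40S ribosomal protein S23	Nontoxin	510	97	51.2	K	K	synonymous
6-phosphogluconate dehydrogenase	Nontoxin	33	624	54.5	V	V	synonymous
60S ribosomal protein L29	Nontoxin	411	45	51.3	K	K	synonymous
60S ribosomal protein L32	Nontoxin	525	332	47.8	K	K	synonymous
Actin-related protein 2/3 complex subunit 3	Nontoxin	30	255	50.0	R	R	synonymous
Alanine aminotransferase 2-like protein	Nontoxin	23	241	43.5	T	T	synonymous
Alpha globin	Nontoxin	26	435	50.0	F	L	nonsynonymous
Aminopeptidase N	Nontoxin	32	2592	46.9	R	C	nonsynonymous
Annexin A2	Nontoxin	66	302	42.4	T	A	nonsynonymous
Annexin A4	Nontoxin	286	248	44.4	A	A	synonymous
Annexin A5	Nontoxin	99	236	50.5	S	S	synonymous
ATP synthase H+ transporting mitochondrial F0	Nontoxin	109	178	45.9	L	L	synonymous
Bifunctional heparan sulfate N-deacetylase/N-sulfotransferase 2-like protein	Nontoxin	20	2445	45.0	M	T	nonsynonymous
C4orf34	Nontoxin	1021	175	48.5	A	A	synonymous
Caprin-1	Nontoxin	46	1327	45.7	S	P	nonsynonymous
Cell cycle progression protein 1	Nontoxin	22	708	45.5	G	G	synonymous
Cell cycle progression protein 1	Nontoxin	52	2286	42.3	K	E	nonsynonymous
Cellular nucleic acid-binding protein	Nontoxin	83	156	56.6	T	T	synonymous
Chloride intracellular channel protein 1	Nontoxin	112	447	58.0	D	D	synonymous
Clathrin interactor 1	Nontoxin	36	1731	50.0	P	P	synonymous
Cyclic AMP-responsive element-binding protein 3	Nontoxin	25	482	44.0	D	D	synonymous
Cytochrome c oxidase subunit 4	Nontoxin	76	227	47.4	E	A	nonsynonymous
Dynactin subunit 6 1	Nontoxin	35	424	51.4	I	I	synonymous
Ectonucleoside triphosphate diphosphohydrolase 7	Nontoxin	27	901	48.1	K	E	nonsynonymous
Endoplasmic reticulum oxidoreductin 1-Lbeta	Nontoxin	260	1247	54.6	G	G	synonymous
EPS8	Nontoxin	49	2112	49.0	Q	H	nonsynonymous
Eukaryotic initiation factor 4A-1	Nontoxin	29	409	44.8	H	H	synonymous
Eukaryotic initiation factor 4A-1	Nontoxin	24	496	41.7	R	R	synonymous
Eukaryotic initiation factor 4A-1	Nontoxin	32	559	53.1	D	D	synonymous
Eukaryotic translation elongation factor 1 gamma	Nontoxin	313	908	50.5	I	I	synonymous
Eukaryotic translation initiation factor (i)	Nontoxin	43	73	41.9	I	I	synonymous
Eukaryotic translation initiation factor (ii)	Nontoxin	40	1067	47.5	H	H	synonymous
Eukaryotic translation initiation factor 2 subunit	Nontoxin	37	1172	51.4	L	L	synonymous
Eukaryotic translation initiation factor 3	Nontoxin	42	3200	52.4	G	G	synonymous
Eukaryotic translation initiation factor 5A-1	Nontoxin	71	77	45.1	D	D	synonymous
Eukaryotic translation initiation factor 5A-1	Nontoxin	75	86	45.3	T	T	synonymous
Eukaryotic translation initiation factor 5A-1	Nontoxin	98	143	48.0	N	N	synonymous
Eukaryotic translation initiation factor 5A-1	Nontoxin	139	384	56.1	R	R	synonymous
Eukaryotic translation initiation factor 5A-1	Nontoxin	108	447	52.8	S	S	synonymous
Eukaryotic translation initiation factor 5A-1	Nontoxin	72	486	54.2	T	T	synonymous
Fructose-1,6-bisphosphatase 1	Nontoxin	54	1078	44.4	R	R	synonymous
GABA	Nontoxin	31	144	45.2	R	R	synonymous
GABA	Nontoxin	42	159	54.8	D	D	synonymous
Guanine nucleotide-binding protein	Nontoxin	30	569	46.7	A	T	nonsynonymous
Guanine nucleotide-binding protein subunit beta-2	Nontoxin	541	149	51.2	T	T	synonymous
Hydroxyacylglutathione hydrolase	Nontoxin	21	190	52.4	W	R	nonsynonymous
Hydroxyacylglutathione hydrolase	Nontoxin	23	709	47.8	S	P	nonsynonymous
Integrin-linked protein kinase	Nontoxin	29	1205	55.2	A	A	synonymous
Interferon-related developmental regulator 2	Nontoxin	22	709	45.5	A	T	nonsynonymous
LAG1 longevity assurance protein 2	Nontoxin	41	896	53.7	T	T	synonymous
LAMTOR2	Nontoxin	81	468	53.1	L	L	synonymous
LIM domain and actin-binding protein	Nontoxin	28	1516	50.0	V	A	nonsynonymous
Lysine-specific histone demethylase 1B	Nontoxin	70	122	44.3	D	G	nonsynonymous
Lysosomal cobalamin transporter	Nontoxin	27	184	48.1	A	A	synonymous
Malate dehydrogenase	Nontoxin	68	1059	57.4	L	L	synonymous
Mannose-1-phosphate guanyltransferase beta	Nontoxin	32	698	53.1	P	S	nonsynonymous
Microspherule protein 1	Nontoxin	24	665	50.0	V	A	nonsynonymous
Minor histocompatibility antigen H13 1	Nontoxin	452	1164	53.5	P	L	nonsynonymous
MTP4	Nontoxin	1664	503	59.3	D	D	synonymous
MTP4	Nontoxin	1480	1621	49.8	P	S	nonsynonymous
NADH dehydrogenase	Nontoxin	40	213	40.0	I	V	nonsynonymous
NADPH-cytochrome P450 oxidoreductase	Nontoxin	28	286	53.6	T	T	synonymous
Nuclease-sensitive element-binding protein 1	Nontoxin	91	675	56.0	R	R	synonymous
Polyubiquitin-C isoform 2	Nontoxin	892	350	57.4	G	G	synonymous
Polyubiquitin-C isoform 2	Nontoxin	637	560	52.3	F	F	synonymous
Polyubiquitin-C isoform 2	Nontoxin	593	635	51.8	K	K	synonymous
Polyubiquitin-C isoform 2	Nontoxin	774	917	52.8	A	A	synonymous
Polyubiquitin-C isoform 2	Nontoxin	697	950	49.6	S	S	synonymous
Proteasome	Nontoxin	83	430	59.0	F	F	synonymous
Proteasome subunit alpha type-6	Nontoxin	48	139	52.1	H	H	synonymous
Protein disulfide-isomerase A3	Nontoxin	146	196	50.0	C	C	synonymous
Sarcolemmal membrane-associated protein-3	Nontoxin	21	1534	42.9	Q	Q	synonymous
SEC31	Nontoxin	110	2866	46.4	P	P	synonymous
Serine/threonine-protein phosphatase	Nontoxin	22	1144	40.9	T	S	nonsynonymous
Serine/threonine-protein phosphatase	Nontoxin	22	1337	45.5	S	S	synonymous
Sialin	Nontoxin	23	321	43.5	P	P	synonymous
Sodium/glucose cotransporter 4	Nontoxin	26	579	57.7	S	C	nonsynonymous
Sodium/glucose cotransporter 4	Nontoxin	26	580	57.7	S	T	nonsynonymous
Stress-induced-phosphoprotein 1	Nontoxin	22	455	50.0	L	L	synonymous
Stress-induced-phosphoprotein 1	Nontoxin	21	716	52.4	K	K	synonymous
Transmembrane emp24 domain-containing	Nontoxin	347	595	46.1	Y	Y	synonymous
Tubulin beta-5 chain	Nontoxin	27	1340	44.4	A	A	synonymous
V-type proton ATPase catalytic subunit A	Nontoxin	63	1344	55.6	I	I	synonymous
Y box binding protein 1	Nontoxin	91	811	59.3	R	R	synonymous
YTH domain family protein 1	Nontoxin	25	1347	44.0	P	P	synonymous
C-type lectin 1a	Toxin	7320	360	55.1	G	G	synonymous
C-type lectin 2	Toxin	130	598	48.5	N	N	synonymous
Cysteine-rich with EGF-like domain 1	Toxin	48	257	50.0	K	K	synonymous
Cysteine-rich with EGF-like domain 1	Toxin	82	949	45.1	T	T	synonymous
Kunitz inhibitor 1a	Toxin	12402	280	42.5	G	R	nonsynonymous
L-amino acid oxidase 1a	Toxin	1850	769	55.0	Y	Y	synonymous
L-amino acid oxidase 1a	Toxin	3094	1158	41.2	H	Q	nonsynonymous
Long chain neurotoxin 3	Toxin	7081	402	40.1	V	I	nonsynonymous
Phospholipase A2 31	Toxin	20	62	40.0	S	S	synonymous
Phospholipase A2 9	Toxin	68	44	50.0	N	I	nonsynonymous
Venom nerve growth factor 1a	Toxin	3689	316	49.3	P	S	nonsynonymous
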