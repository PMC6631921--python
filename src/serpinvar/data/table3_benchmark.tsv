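# 57-variant SERPINA1 benchmark: 17 ClinVar-pathogenic and 5 ClinVar-benign human
# variants plus 35 neutral variants observed in primate orthologs (source species and
# pairwise sequence identity recorded; two entries list both source orthologs).
# Scores: SVM pathogenicity probability, FoldX ddG (kcal/mol), PolyPhen-2 v2.2.2.
# Mature AAT numbering throughout. label is the truth class used for benchmarking.
variant	subset	species	identity	svm	foldx_ddg	polyphen2	label
P369L	clinvar_pathogenic	Homo sapiens	100	0.8496	1.510	1.0000	pathogenic
P369S	clinvar_pathogenic	Homo sapiens	100	0.8353	4.410	1.0000	pathogenic
P369T	clinvar_pathogenic	Homo sapiens	100	0.8599	2.810	1.0000	pathogenic
M358R	clinvar_pathogenic	Homo sapiens	100	0.7853	0.431	0.0190	pathogenic
E342K	clinvar_pathogenic	Homo sapiens	100	0.8413	2.090	1.0000	pathogenic
E264V	clinvar_pathogenic	Homo sapiens	100	0.8619	1.660	1.0000	pathogenic
D256V	clinvar_pathogenic	Homo sapiens	100	0.8708	1.950	0.9850	pathogenic
G225R	clinvar_pathogenic	Homo sapiens	100	0.8975	5.160	0.9820	pathogenic
R223C	clinvar_pathogenic	Homo sapiens	100	0.8954	-0.350	0.9950	pathogenic
I92N	clinvar_pathogenic	Homo sapiens	100	0.8215	3.600	1.0000	pathogenic
G67E	clinvar_pathogenic	Homo sapiens	100	0.8680	26.290	1.0000	pathogenic
S53F	clinvar_pathogenic	Homo sapiens	100	0.8687	19.860	1.0000	pathogenic
L41P	clinvar_pathogenic	Homo sapiens	100	0.7585	3.240	0.6010	pathogenic
R39C	clinvar_pathogenic	Homo sapiens	100	0.8672	2.110	1.0000	pathogenic
A336T	clinvar_pathogenic	Homo sapiens	100	0.8479	3.450	1.0000	pathogenic
G115S	clinvar_pathogenic	Homo sapiens	100	0.7826	1.610	0.9990	pathogenic
F52S	clinvar_pathogenic	Homo sapiens	100	0.7900	6.020	1.0000	pathogenic
E376D	clinvar_benign	Homo sapiens	N/A	0.2991	1.850	0	benign
E363K	clinvar_benign	Homo sapiens	N/A	0.4172	-0.900	0.11	benign
A284S	clinvar_benign	Homo sapiens	N/A	0.3445	-0.240	0.139	benign
V213A	clinvar_benign	Homo sapiens	N/A	0.1161	-0.100	0	benign
R101H	clinvar_benign	Homo sapiens	N/A	0.0576	-0.533	0	benign
P21Q	primate	Hylobates sp. ECACC	95	0.363	0.72	0.014	benign
F23L	primate	Papio anubis	92	0.3762	0.38	0	benign
T27A	primate	Gorilla gorilla	98	0.4118	1.34	0	benign
N29K	primate	Hylobates sp. ECACC	95	0.4365	-0.63	0.178	benign
N29S	primate	Papio anubis	92	0.0839	0.13	0	benign
T48S	primate	Hylobates sp. ECACC	95	0.4991	0.51	0	benign
I50V	primate	Gorilla gorilla	98	0.6687	0.96	0.767	benign
D74S	primate	Chlorocebus sabaeus	92	0.0588	0.38	0	benign
N81H	primate	Pongo abelii	96	0.462	0.27	0.007	benign
I92V	primate	Pongo abelii;Hylobates sp. ECACC	96;95	0.7931	1.06	0.006	benign
Q105K	primate	Papio anubis	92	0.2178	-0.5	0.001	benign
N116S	primate	Gorilla gorilla	98	0.751	1.9	0.311	benign
K136N	primate	Papio anubis	92	0.4292	0.07	0	benign
E141D	primate	Pongo abelii	96	0.4052	0.77	0.002	benign
G148E	primate	Chlorocebus sabaeus	92	0.219	-0.46	0	benign
D159N	primate	Papio anubis	92	0.165	-1.21	0	benign
Q212E	primate	Pongo abelii	96	0.2568	0.35	0	benign
V213A	primate	Hylobates sp. ECACC	95	0.1161	-0.1	0	benign
Q230Y	primate	Papio anubis	92	0.0803	0.49	0	benign
Q230H	primate	Hylobates sp. ECACC	95	0.0545	0.41	0	benign
K233E	primate	Papio anubis	92	0.0787	0.58	0	benign
D270E	primate	Hylobates sp. ECACC	95	0.2543	-0.03	0	benign
I271V	primate	Gorilla gorilla	98	0.1015	0.52	0	benign
D280N	primate	Pongo abelii	96	0.1407	0.82	0	benign
S285N	primate	Chlorocebus sabaeus	92	0.0554	-1.6	0	benign
S292A	primate	Chlorocebus sabaeus	92	0.3206	-0.14	0.003	benign
S301R	primate	Pongo abelii	96	0.1328	-0.54	0.011	benign
S301T	primate	Hylobates sp. ECACC	95	0.0724	0	0	benign
S313G	primate	Hylobates sp. ECACC	95	0.606	0.63	0.05	benign
E324D	primate	Chlorocebus sabaeus	92	0.0978	0.62	0	benign
A332V	primate	Homo sapiens	99	0.1255	1.88	0.99	benign
I360V	primate	Gorilla gorilla	98	0.1547	0.73	0	benign
L383H	primate	Hylobates sp. ECACC	95	0.8834	3.08	1	benign
M385I	primate	Papio anubis	92	0.7686	3.15	0.001	benign
M385V	primate	Pan troglodytes;Pongo abelii	99;96	0.7566	2.44	0.001	benign
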