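# Predictor scores for 16 rare/novel SERPINA1 missense variants: SVM pathogenicity
# probability, FoldX PositionScan ddG (kcal/mol; N/A where the residue is absent from
# the structure) and PolyPhen-2 v2.2.2 score. Mature AAT numbering unless the scheme
# column says precursor. rsid gives the dbSNP accession where one is known.
variant	scheme	svm	foldx_ddg	polyphen2	rsid
P289S	mature	0.8282	3.49	1.000	rs779938258
I50N	mature	0.8153	2.69	1.000	rs1275309068
D341V	mature	0.8651	0.99	0.998	rs864622046
M221T	mature	0.8186	2.93	0.997	rs766260108
V210E	mature	0.7162	1.37	0.818	rs746197812
P28L	mature	0.8205	1.17	0.648	rs944607375
P369H	mature	0.8784	3.36	1.000	.
A142D	mature	0.7958	1.03	0.992	rs142942004
M385T	mature	0.8722	3.34	0.134	rs1488213352
V333M	mature	0.7237	-0.25	0.990	rs373630097
I9N	precursor	0.3387	N/A	0.517	rs1296175763
Q40R	mature	0.6589	-0.35	0.018	rs763483402
K174E	mature	0.5053	0.21	0.030	rs766034720
H262Y	mature	0.6708	-0.68	0.040	rs149537225
E204K	mature	0.1021	-0.70	0.000	rs199422208
A325P	mature	0.0878	0.72	0.000	rs376024688
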