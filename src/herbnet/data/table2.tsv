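rank	uniprot_ac	protein_name	gene_symbol	degree	organism
1	P35228	Nitric oxide synthase, inducible	NOS2	25	Homosapiens
2	P23219	Prostaglandin G/H synthase 1	PTGS1	23	Homosapiens
3	P03372	Estrogen receptor	ESR1	34	Homosapiens
4	P37231	Peroxisome proliferator-activated receptor gamma	PPARG	21	Homosapiens
5	P35354	Prostaglandin G/H synthase 2	PTGS2	27	Homosapiens
6	Q92731	Estrogen receptor beta	ESR2	17	Homosapiens
7	P11388	DNA topoisomerase 2-alpha	TOP2A	5	Homosapiens
8	P16389	Potassium voltage-gated channel subfamily H member 2	KCNH2	13	Homosapiens
9	P08709	Coagulation factor VII	F7	6	Homosapiens
10	P29474	Nitric-oxide synthase, endothelial	NOS3	21	Homosapiens
11	P27338	Amine oxidase [flavin-containing] B	MAOB	5	Homosapiens
12	Q04206	Transcription factor p65	RELA	6	Homosapiens
13	P00533	Epidermal growth factor receptor	EGFR	1	Homosapiens
14	P31749	RAC-alpha serine/threonine-protein kinase	AKT1	2	Homosapiens
15	P15692	Vascular endothelial growth factor A	VEGFA	2	Homosapiens
16	P24385	G1/S-specific cyclin-D1	CCND1	3	Homosapiens
17	P10415	Apoptosis regulator Bcl-2	BCL2	5	Homosapiens
18	P01100	Proto-oncogene c-Fos	FOS	3	Homosapiens
19	P38936	Cyclin-dependent kinase inhibitor 1	CDKN1A	4	Homosapiens
20	P55211	Caspase-9	CASP9	4	Homosapiens
21	P00749	Urokinase-type plasminogen activator	PLAU	4	Homosapiens
22	P08253	72 kDa type IV collagenase	MMP2	2	Homosapiens
23	P14780	Matrix metalloproteinase-9	MMP9	2	Homosapiens
24	P22301	Interleukin-10	IL10	1	Homosapiens
25	P01133	Proepidermal growth factor	EGF	1	Homosapiens
26	P06400	Retinoblastoma-associated protein	RB1	2	Homosapiens
27	P01375	Tumor necrosis factor	TNF	6	Homosapiens
28	P05412	Transcription factor AP-1	JUN	4	Homosapiens
29	P05231	Interleukin-6	IL-6	3	Homosapiens
30	P42574	Caspase-3	CASP3	7	Homosapiens
31	P04637	Cellular tumor antigen p53	TP53	4	Homosapiens
32	P11926	Ornithine decarboxylase	ODC1	1	Homosapiens
33	Q14790	Caspase-8	CASP8	3	Homosapiens
34	P00441	Superoxide dismutase [Cu-Zn]	SOD1	2	Homosapiens
35	P17252	Protein kinase C alpha type	PRKCA	2	Homosapiens
36	P03956	Interstitial collagenase	MMP1	3	Homosapiens
37	P42224	Signal transducer and activator of transcription 1-alpha/beta	STAT1	2	Homosapiens
38	P04626	Receptor tyrosine-protein kinase erbB-2	ERBB2	1	Homosapiens
39	P09601	Heme oxygenase 1	HMOX1	3	Homosapiens
40	P05177	Cytochrome P450 1A2	CYP1A2	2	Homosapiens
41	P01106	Myc proto-oncogene protein	MYC	1	Homosapiens
42	P05362	Intercellular adhesion molecule 1	ICAM1	4	Homosapiens
43	P01584	Interleukin-1 beta	IL1B	5	Homosapiens
44	P13500	C-C motif chemokine 2	CCL2	1	Homosapiens
45	P19320	Vascular cell adhesion protein 1	VCAM1	2	Homosapiens
46	P10145	Interleukin-8	CXCL8	2	Homosapiens
47	P05771	Protein kinase C beta type	PRKCB	2	Homosapiens
48	O15392	Baculoviral IAP repeat-containing protein 5	BIRC5	2	Homosapiens
49	P04792	Heat shock protein beta-1	HSPB1	1	Homosapiens
50	P01137	Transforming growth factor beta-1	TGFB1	3	Homosapiens
51	P60568	Interleukin-2	IL2	2	Homosapiens
52	Q16678	Cytochrome P450 1B1	CYP1B1	2	Homosapiens
53	P00750	Tissue-type plasminogen activator	PLAT	1	Homosapiens
54	P01579	Interferon gamma	IFNG	4	Homosapiens
55	P09917	Arachidonate 5-lipoxygenase	ALOX5	3	Homosapiens
56	P60484	Phosphatidylinositol-3,4,5-trisphosphate 3-phosphatase and dual-specificity protein phosphatase PTEN	PTEN	1	Homosapiens
57	P05164	Myeloperoxidase	MPO	1	Homosapiens
58	Q9UNQ0	ATP-binding cassette subfamily G member 2	ABCG2	1	Homosapiens
59	P09211	Glutathione S-transferase P	GSTP1	3	Homosapiens
60	Q16236	Nuclear factor erythroid 2-related factor 2	NFE2L2	1	Homosapiens
61	P15559	NAD(P)H dehydrogenase [quinone] 1	NQO1	2	Homosapiens
62	P09874	Poly [ADP-ribose] polymerase 1	PARP1	1	Homosapiens
63	P35869	Aryl hydrocarbon receptor	AHR	2	Homosapiens
64	P19875	C-X-C motif chemokine 2	CXCL2	1	Homosapiens
65	O96017	Serine/threonine-protein kinase Chk2	CHEK2	1	Homosapiens
66	Q07869	Peroxisome proliferator-activated receptor alpha	PPARA	1	Homosapiens
67	P02741	C-reactive protein	CRP	1	Homosapiens
68	P02778	C-X-C motif chemokine 10	CXCL10	1	Homosapiens
69	Q9NS23	Ras association domain-containing protein 1	RASSF1	1	Homosapiens
70	P17936	Insulin-like growth factor-binding protein 3	IGFBP3	1	Homosapiens
71	P01344	Insulin-like growth factor II	IGF2	1	Homosapiens
72	P21860	Receptor tyrosine-protein kinase erbB-3	ERBB3	1	Homosapiens
73	P09488	Glutathione S-transferase Mu 1	GSTM1	2	Homosapiens
74	P28223	5-Hydroxytryptamine 2A receptor	HTR2A	4	Homosapiens
75	P84022	Mothers against decapentaplegic homolog 3	SMAD3	1	Homosapiens
76	P08588	Beta-1 adrenergic receptor	ADRB1	3	Homosapiens
77	P29466	Caspase-1	CASP1	2	Homosapiens
78	P18509	Pituitary adenylate cyclase-activating polypeptide	ADCYAP1	1	Homosapiens
79	O95456	Proteasome assembly chaperone 1	PSMG1	1	Homosapiens
80	P05112	Interleukin-4	IL-4	1	Homosapiens
81	P00325	Alcohol dehydrogenase 1B	ADH1B	1	Homosapiens
82	P28702	Retinoic acid receptor RXR-beta	RXRB	1	Homosapiens
83	P04040	Catalase	CAT	1	Homosapiens
84	P01308	Insulin	INS	1	Homosapiens
85	P21731	Thromboxane A2 receptor	TBXA2R	1	Homosapiens
86	P07858	Cathepsin B	CTSB	1	Homosapiens
87	P40763	Signal transducer and activator of transcription 3	STAT3	1	Homosapiens
88	Q00534	Cell division protein kinase 6	CDK6	1	Homosapiens
89	P09038	Heparin-binding growth factor 2	FGF2	1	Homosapiens
90	P15336	Cyclic AMP-dependent transcription factor ATF-2	ATF2	1	Homosapiens
91	P04141	Granulocyte-macrophage colony-stimulating factor	CSF2	1	Homosapiens
92	P17677	Neuromodulin	GAP43	1	Homosapiens
93	P18031	Tyrosine-protein phosphatase nonreceptor type 1	PTPN1	1	Homosapiens
94	P30279	G1/S-specific cyclin-D2	CCND2	1	Homosapiens
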