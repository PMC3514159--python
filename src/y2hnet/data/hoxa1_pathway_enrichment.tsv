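pathway_name	pathway_id	obs	odds_ratio	fdr	corr_fdr	source	gene_symbols	entrez_ids
RXR and RAR hetrodimerization with other nuclear receptor	pc926	2	24,83	2,00E-05	2,40E-03	NCI-Nature	FAM120B,NR1H2	84498,7376
Cell adhesion molecules (CAMs) - Homo sapiens (human)	hsa04514	2	19,70	9,00E-05	1,35E-02	KEGG	CLDN2,PVRL2	9075,5819
Gap junction - Homo sapiens (human)	hsa04540	2	16,59	8,00E-05	1,20E-02	KEGG	GNAI2,PDGFRB	2771,5159
Signaling events mediated by PTP1B	pc948	4	12,72	1,00E-05	1,20E-03	NCI-Nature	CRK,SPRY2,TRPV6,PDGFRB	1398,10253,55503,5159
Retinoic acid receptors-mediated signaling	pc960	3	10,19	2,10E-04	2,52E-02	NCI-Nature	NR1H2,NRIP1,FAM120B	7376,8204,84498
Integrins in angiogenesis	pc989	3	10,04	3,40E-04	4,08E-02	NCI-Nature	CDKN1B,SPP1,VCL	1027,6696,7414
Down-stream signal transduction	pc690	2	8,28	5,00E-05	3,14E-02	Reactome	PDGFRB,NCK2	5159,8440
Signaling by PDGF	pc876	2	8,28	5,00E-05	3,14E-02	Reactome	PDGFRB,NCK2	5159,8440
Toll-like receptor signaling pathway - Homo sapiens (human)	hsa04620	3	7,54	3,20E-04	4,80E-02	KEGG	TRAF6,TOLLIP,SPP1	7189,54472,6696
Homologous recombination - Homo sapiens (human)	hsa03440	2	7,18	1,40E-04	2,10E-02	KEGG	TOP3B,RAD54B	8940,25788
LPA receptor mediated events	pc1042	4	7,07	1,30E-04	1,56E-02	NCI-Nature	BIRC2,TRIP6,TRAF6,CRK	329,7205,7189,1398
Focal adhesion - Homo sapiens (human)	hsa04510	8	6,55	3,00E-05	4,50E-03	KEGG	SPP1,VCL,VASP,CRK,PDGFRB,BIRC2,CCND3,PAK7	6696,7414,7408,1398,5159,329,896,57144
TCR signaling in naive CD4+ T cells	pc1031	4	6,54	3,00E-04	3,60E-02	NCI-Nature	BIRC2,TRAF6,GRAP2,TRPV6	329,7189,9402,55503
Axon guidance - Homo sapiens (human)	hsa04360	5	6,50	1,40E-04	2,10E-02	KEGG	GNAI2,PAK7,NTN4,ABLIM1,NCK2	2771,57144,59277,3983,8440
TCR signaling in naive CD8+ T cells	pc997	4	6,34	3,80E-04	4,56E-02	NCI-Nature	TRAF6,GRAP2,TRPV6,BIRC2	7189,9402,55503,329
Lysine degradation - Homo sapiens (human)	hsa00310	3	6,28	1,00E-04	1,50E-02	KEGG	OGDH,AASDHPPT,EHMT2	4967,60496,10919
IGF1 pathway	pc1041	3	6,26	3,60E-04	4,32E-02	NCI-Nature	CRK,NCK2,YWHAE	1398,8440,7531
p75(NTR)-mediated signaling	pc978	5	6,02	2,60E-04	3,12E-02	NCI-Nature	YWHAE,TRAF6,BIRC2,RTN4,LINGO1	7531,7189,329,57142,84894
Proteogylcan syndecan-mediated signaling events	pc1045	5	5,53	2,20E-04	2,64E-02	NCI-Nature	BSG,HGS,CRK,SPRY2,SPP1	682,9146,1398,10253,6696
Syndecan-1-mediated signaling events	pc974	3	5,46	1,60E-04	1,92E-02	NCI-Nature	BSG,CRK,HGS	682,1398,9146
Plasma membrane estrogen receptor signaling	pc1048	6	4,07	3,60E-04	4,32E-02	NCI-Nature	CRK,SLC9A1,IRF4,NCK2,YWHAE,TRAF6	1398,6548,3662,8440,7531,7189
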