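symbol	entrez_id	uniprot_acc	name	function_note	configs	previously_described	copurification	bifc
ADCK4	79934	Q96D53	aarF domain containing kinase 4	Ser/Thr kinase	AD	0	N	/
AGPAT1	10554	Q99943	1-acylglycerol-3-phosphate O-acyltransferase 1	Acetyltransferase	AD	0	N	/
BSCL2 (Seipin)	26580	Q96G97	Berardinelli-Seip congenital lipodystrophy 2	Unknown	AD	0	N	/
DKKL1 (Soggy)	27120	Q9UK85	dickkopf-like 1	Signaling modulator (Wnt pathway)	AD	0	N	/
EFEMP2*§	30008	O95967	EGF-containing fibulin-like extracellular matrix protein 2	Fibulin-like, unknown	AD	1	Y	n.d.
FAM108A1	81926	Q96GS6	family with sequence similarity 108, member A1	unknown	AD	0	Y	Nuclear
GP9	2815	P14770	glycoprotein IX (platelet)	Multifunctional receptor, cytoskeleton and signaling regulator (integrins, focal adhesion, PI3K)	AD	0	N	/
GRN*	2896	P28799	granulin	Growth factor, transcription factor (in GRN precursor form)	AD	1	Y	n.d.
HOXA1§	3198	P49639	homeobox A1	Transcription factor (homeodomain)	AD	0	Y	Nuclear
HSD3B7	80270	Q9H2F3	hydroxy-delta-5-steroid dehydrogenase, 3 β- and steroid delta-isomerase 7	Dehydrogenase	AD	0	N	/
IKZF2 (Helios)	22807	Q9UKS7	IKAROS family zinc finger 2	Transcription fator (zinc finger)	AD	0	Y	Nuclear
KRT81	3887	Q14533	keratin 81	Intermediate filament	AD	0	Y	Nuclear and cytoplasmic
KRTAP26-1§	388818	Q6PEX3	keratin associated protein 26-1	Keratin associated	AD	0	Y	Nuclear
KRTAP3-2§	83897	Q9BYR7	keratin associated protein 3-2	Keratin associated	AD	0	Y	Nuclear
KRTAP3-3§	85293	Q9BYR6	keratin associated protein 3-3	Keratin associated	AD	0	N	/
KRTAP4-12*§	83755	Q9BQ66	keratin associated protein 4-12	Keratin associated	AD	1	Y	Cytoplasmic
KRTAP5-9	3846	P26371	keratin associated protein 5-9	Keratin associated	AD	0	Y	Vesicular and cytoplasmic
LIMS1 (PINCH1)	3987	P48059	LIM and senescent cell antigen-like domains 1	Cytoskeleton and signaling regulator (focal adhesion, integrins, receptor tyrosine kinases)	AD	0	Y	Nuclear
MDFI* (I-mfa)	4188	Q99750	MyoD family inhibitor	Signaling regulator (channels, Wnt, JNK pathways) - Transcription factor (I-mfa domain),	AD	1	Y	Nuclear, vesicular, cytoplasmic
PCSK5§	5125	Q92824	proprotein convertase subtilisin/kexin type 5	Pro-protein convertase	AD	0	N	/
PDCD6IP (Alix)	10015	Q8WUM4	programmed cell death 6 interacting protein	Endosome formation and vesicular trafficking, cytoskeleton and signaling regulator (Focal adhesion, TNFR pathway, EGFR, PDGFR)	AD	0	Y	Vesicular and cytoplasmic
PFKM	5213	P08237	phosphofructokinase, muscle	Glycolysis	AD	0	N	/
PITX2	5308	Q99697	paired-like homeodomain 2	Transcription factor (homeodomain)	AD	0	Y	Nuclear
PLSCR4§	57088	Q9NRQ2	phospholipid scramblase 4	Phospholipid scramblase, transcription factor	AD	0	Y	Nuclear
RAB33A	9363	Q14088	member RAS oncogene family	Small GTPase, vesicular trafficking (Ras pathway)	AD	0	Y	Nuclear
SMOC1	64093	Q9H4F8	SPARC related modular calcium binding 1	Extracellular matrix protein, signaling, migration and differentiation modulator	AD	0	Y	n.d.
TRAPPC6A*	79090	O75865	trafficking protein particle complex 6A	Vesicular trafficking	AD	1	Y	Nuclear
ZZZ3	26009	Q8IYH5	zinc finger, ZZ-type containing 3	Transcription factor (zinc finger)	AD	0	Y	Nuclear
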