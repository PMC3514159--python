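symbol	entrez_id	uniprot_acc	name	function_note	configs	previously_described	copurification	bifc
ADAMTSL4 (TSRC1)	54507	Q6UY14	ADAMTS-like 4	TNF-induced apopotosis	DB	0	Y	Nuclear
BAT2L	84726	Q5JSZ5	HLA-B associated transcript 2-like	Unknown	DB	0	Y	Nuclear
C1orf94	84970	Q6P1W5	chromosome 1 open reading frame 94	Protein binding	DB	0	Y	Cytoplasmic
CCDC33	80125	Q8N5R6	coiled-coil domain containing 33	Protein binding	DB	0	N	/
EFCAB4B	84766	Q9BSW2	EF-hand calcium binding domain 4B	Calcium binding	DB	0	Y	Nuclear, and vesicular
EFEMP2*§	30008	O95967	EGF-containing fibulin-like extracellular matrix protein 2	Fibulin-like, unknown	DB	1	Y	n.d.
FAM154A	158297	Q8IYX7	family with sequence similarity 154, member A	Unknown	DB	0	Y	Nuclear, vesicular, cytoplasmic
FHL5 (ACT)	9457	Q5TD97	four and a half LIM domains 5	Transcription factor (zinc finger), and kinesin and actin-binding protein	DB	0	Y	Nuclear
GPRIN2	9721	O60269	G protein regulated inducer of neurite outgrowth 2	G protein interaction	DB	0	N	/
HOXA1§	3198	P49639	homeobox A1	Transcription factor (homeodomain)	DB	0	Y	Nuclear
HOXD3	3232	P31249	homeobox D3	Transcription factor (homeodomain)	DB	0	Y	Nuclear
HSFY1	86614	Q96LI6	heat shock transcription factor, Y-linked 1	Transcription factor (heatshock factor)	DB	0	N	/
KRTAP26-1§	388818	Q6PEX3	keratin associated protein 26-1	Keratin associated	DB	0	Y	Nuclear
KRTAP3-2§	83897	Q9BYR7	keratin associated protein 3-2	Keratin associated	DB	0	Y	Nuclear
KRTAP3-3§	85293	Q9BYR6	keratin associated protein 3-3	Keratin associated	DB	0	N	/
KRTAP4-12*§	83755	Q9BQ66	keratin associated protein 4-12	Keratin associated	DB	1	Y	Cytoplasmic
LGALS13	29124	Q9UHV8	lectin, galactoside-binding, soluble, 13	Lipase activity, signaling (regulator of protein kinases)	DB	0	Y	Nuclear, vesicular, cytoplasmic
LNX2	222484	Q8N448	ligand of numb-protein X 2	Molecular scaffold, E3 ubiquitin ligase, signaling regulator (Notch), associated to cell adhesion molecules	DB	0	Y	Nuclear and cytoplasmic
LPXN*	9404	O60711	leupaxin	Signaling (focal adhesion), Transcription factor	DB	1	Y	Vesicular and cytoplasmic
MGAT5B (GnT-VB)	146664	Q3V5L5	mannosyl (α-1,6-)-glycoprotein β-1,6-N-acetyl-glucosaminyltransferase, isozyme B	Glycosyltransferase, focal adhesion dynamics	DB	0	Y	Nuclear
N4BP2L2 (PFAAP5)	10443	Q92802	NEDD4 binding protein 2-like 2	Transcription factor or co-regulator	DB	0	Y	Nuclear
NR4A1 (Nur77)	3164	P22736	nuclear receptor subfamily 4, group A, member 1	Transcription factor (nuclear hormone receptor)	DB	0	N	/
OGT	8473	O15294	O-linked N-acetylglucosamine (GlcNAc) transferase	Glycosyltransferase, transcription co-regulator	DB	0	Y	Nuclear and cytoplasmic
PCSK5§	5125	Q92824	proprotein convertase subtilisin/kexin type 5	Pro-protein convertase	DB	0	N	/
PDLIM7 (LMP-1)	9260	Q9NR12	PDZ and LIM domain 7	Signaling regulator (BMP, IGFBP pathways)	DB	0	Y	Cytoplasmic
PLSCR1*	5359	O15162	phospholipid scramblase 1	Phospholipid scramblase, signaling regulatior (receptor tyrosine kinases, protein kinases), transcription factor	DB	1	Y	Nuclear
PLSCR4§	57088	Q9NRQ2	phospholipid scramblase 4	Phospholipid scramblase, transcription factor	DB	0	Y	Nuclear
PRDM14	63978	Q9G2V8	PR domain containing 14	Histone methyltransferase	DB	0	Y	Nuclear, vesicular, cytoplasmic
RBCK1	10616	Q9BYM8	RanBP-type and C3HC4-type zinc finger containing 1	Signaling regulator (TNFR, protein kinases), ubiquitin ligase, transcription factor	DB	0	Y	Nuclear, vesicular, cytoplasmic
RBPMS (Hermes)	11030	Q93062	RNA binding protein with multiple splicing	Signaling regulator (TGFβ), RNA binding	DB	0	Y	Nuclear, vesicular, cytoplasmic
RGS17	26575	Q9UGC6	regulator of G-protein signaling 17	Signaling regulator (G proteins)	DB	0	N	/
RGS20	8601	O76081	regulator of G-protein signaling 20	Signaling regulator (G proteins, protein kinases)	DB	0	Y	Nuclear and cytoplasmic
SPRY1	10252	O43609	sprouty homolog 1	Signaling regulator (receptor tyrosine kinases)	DB	0	Y	Nuclear, vesicular, cytoplasmic
SPRY2	10253	O43597	sprouty homolog 2	Signaling regulator (receptor tyrosine kinases, protein kinases)	DB	0	N	/
TRAF1	7185	Q13077	TNF receptor-associated factor 1	Signaling regulator (TNFR pathway)	DB	0	Y	Vesicular and cytoplasmic
TRAF2	7186	Q12933	TNF receptor-associated factor 2	Signaling regulator (TNFR pathway)	DB	0	Y	Vesicular and cytoplasmic
TRIM23 (ARD1)	373	P36406	tripartite motif-containing 23	Vesicular trafficking and signaling regulator (TNF pathway), E3 ubiquitin ligase	DB	0	Y	n.d.
TRIP6*	7205	Q15654	thyroid hormone receptor interactor 6	Cytoskeleton and signaling regulator (focal adhesion, TNFR), transcription co-regulator	DB	1	Y	Nuclear
ZBTB16 (PLZF)	7704	Q05516	zinc finger and BTB domain containing 16	Transcription factor (zinc finger), signaling regulator (GPCR, ProRenin Receptor)	DB	0	Y	Nuclear and vesicular
ZBTB32 (FAZF)	27033	Q9Y2Y4	zinc finger and BTB domain containing 32	Transcription factor (zinc finger)	DB	0	Y	Cytoplasmic
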