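fly_accession	fly_mw_kda	protein_name	human_accession	human_mw_kda
FBpp0086732	97	WD repeat and HMG-box DNA-binding protein 1	WDHD1	126
FBpp0079771	31	Voltage-dependent anion-selective channel protein 2	VDAC2	32
FBpp0074831	174	UDP-glucose:glycoprotein glucosyltransferase 1	UGGG1	177
FBpp0079606	18	Ubiquitin	UBIQ	9
FBpp0070362	92	Tyrosine-protein phosphatase non-receptor type 11	PTN11/SHP2	68
FBpp0070637	84	tRNA (cytosine-5-)-methyltransferase NSUN2	NSUN2	86
FBpp0081156	28	THO complex subunit 4	THOC4	27
FBpp0082692	131	SWI/SNF complex subunit SMARCC2	SMRC2	133
FBpp0085736	72	Succinate dehydrogenase [ubiquinone] flavoprotein subunit, mitochondrial	DHSA	73
FBpp0074011	77	Splicing factor, proline- and glutamine-rich	SFPQ	76
FBpp0082724	28	Splicing factor, arginine/serine-rich 1	SFRS1	28
FBpp0099974	65	Serine/threonine-protein phosphatase 2A 65 kDa regulatory subunit A alpha isoform	2AAA	65
FBpp0082264	75	Ras GTPase-activating protein-binding protein 2	G3BP2	54
FBpp0086767	70	Rac GTPase-activating protein 1	RGAP1	71
FBpp0072581	99	Puromycin-sensitive aminopeptidase	PSA	103
FBpp0075196	124	Protein phosphatase 1 regulatory subunit 12A	MYPT1	112
FBpp0075278	185	Probable global transcription activator SNF2L4	SMCA4	185
FBpp0087124	280	Pre-mRNA-processing-splicing factor 8	PRP8	274
FBpp0085902	55	Pre-mRNA-processing factor 19	PRP19	55
FBpp0083348	127	Phosphatidylinositol-4,5-bisphosphate 3-kinase catalytic subunit beta isoform	PK3CB	123
FBpp0077791	57	Phosphatidylinositol 3-kinase regulatory subunit gamma (BAIT)	P55G/P85A	54/84
FBpp0088542	71	Nucleolar phosphoprotein p130	NOLC1	74
FBpp0075759	38	Nuclease-sensitive element-binding protein 1	YBOX1	36
FBpp0086971	23	Nascent polypeptide-associated complex subunit alpha, muscle-specific form	NACAM	221
FBpp0078930	135	Liprin-alpha-1	LIPA1	136
FBpp0080637	157	Leucine-rich PPR motif-containing protein, mitochondrial	LPPRC	158
FBpp0073083	101	Kinesin-like protein KIF23	KIF23	110
FBpp0086328	110	Kinesin-1 heavy chain	KINH	110
FBpp0082066	44	Interleukin enhancer-binding factor 2	ILF2	43
FBpp0079677	108	Insulin receptor substrate 1	IRS1	132
FBpp0076408	119	Importin-7	IPO7	120
FBpp0079187	36	Guanine nucleotide-binding protein subunit beta-2-like 1	GBLP	35
FBpp0087977	35	Glyceraldehyde-3-phosphate dehydrogenase	G3P	36
FBpp0086220	82	Far upstream element-binding protein 2	FUBP2	73
FBpp0072151	82	FACT complex subunit SSRP1	SSRP1	81
FBpp0087186	34	Electron transfer flavoprotein subunit alpha, mitochondrial	ETFA	35
FBpp0081568	319	E3 ubiquitin-protein ligase UBR5	UBR5	309
FBpp0075069	45	Cytochrome b-c1 complex subunit 2, mitochondrial	QCR2	48
FBpp0072693	139	Coatomer subunit alpha	COPA	138
FBpp0073966	191	Clathrin heavy chain 1	CLH1	192
FBpp0074865	104	Caprin-1	CAPR1	78
FBpp0082728	68	ATPase family AAA domain-containing protein 3A	ATD3A	71
FBpp0085258	40	Activator of 90 kDa heat shock protein ATPase homolog 1	AHSA1	38
FBpp0081002	85	Aconitate hydratase, mitochondrial	ACON	85
FBpp0070890	44	26S protease regulatory subunit S10B	PRS10	44
FBpp0083843	48	26S protease regulatory subunit 6A	PRS6A	49
FBpp0087500	28	14-3-3 protein zeta/delta	1433Z	28
FBpp0082990	30	14-3-3 protein epsilon	1433E	29
FBpp0079244	170	Platelet-derived growth factor receptor alpha	PGFRA	123
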