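# Prioritised-variant summary table reported by the multiplex-family study this
# package models (inherited + de novo hits with family, trait/diagnosis label,
# site, predictors and evidence tier). Used as the worked-example fixture.
# Notes on transcription:
# - ZBTB18: the printed trait/diagnosis label is garbled ("N /Diagnosis"); it is
#   stored as diagnosis-only, consistent with the study's printed Venn counts.
# - TAF4: one printed row spans two families ("4/21", label "MAP/BAP/Diagnosis");
#   it is split into two records (family 4 -> MAP, family 21 -> BAP). The
#   printed table does not say which family had which trait level; every count
#   computed from this file is invariant to that assignment.
# - The PHLPP1 frameshift deletion keeps the dash-style indel representation
#   ("C/-") used by the source table.
# trait_level "." = no trait label; diagnosis 1 = diagnosis-labelled.
gene	origin	family	trait_level	diagnosis	chrom	pos	ref	alt	aa_change	dbsnp	maf_nfe	sift	polyphen_hdiv	tier	tier_source
KMT2C	inherited	19	MAP	0	7	151932996	C	T	p.G892E	rs372408170	0.0001	D	D	1	DDG2P-monoallelic
ANKRD11	inherited	10	NAP	1	16	89346774	G	T	p.P2059H	rs117997391	0.0075	D	D	1	DDG2P-monoallelic
SETD2	inherited	14	MAP	1	3	47165380	G	A	p.S205F	.	.	D	P	1	DDG2P-monoallelic
SETD2	inherited	10	NAP	1	3	47164711	C	T	p.R428H	rs201984344	0.0004	D	D	1	DDG2P-monoallelic
ATP2B2	inherited	15	BAP	0	3	10392216	G	A	p.R683C	rs754680596	.	D	D	1	SFARI
CUX1	inherited	16	MAP	1	7	101921292	A	C	p.K530Q	rs118010189	0.0071	D	D	1	DDG2P-monoallelic
JADE2	inherited	14	NAP	0	5	133901944	C	T	p.R370C	rs137957798	0.0005	D	D	2	AutDB
MTOR	inherited	25	NAP	0	1	11272478	T	C	p.Y1151C	rs151082401	0.0003	D	D	1	DDG2P-monoallelic
BRPF1	inherited	10	NAP	1	3	9783082	G	A	p.V605M	.	.	D	P	1	DDG2P-monoallelic
ESR1	inherited	10	NAP	1	6	152265352	C	T	p.R269C	rs142712646	0.0008	D	D	2	AutDB
MAP2	inherited	16	MAP	1	2	210559050	G	A	p.G719D	rs148922251	0.0051	D	D	2	AutDB
SEMA3F	inherited	22	MAP	0	3	50225538	C	T	p.P684L	rs754678639	.	D	D	2	AutDB
YTHDC1	inherited	28	BAP	1	4	69203301	C	A	p.D150Y	rs186920853	.	D	D	1	DBDGD
CHD7	inherited	19	.	1	8	61707624	G	T	p.D726Y	rs748119797	.	D	D	1	DDG2P-monoallelic
SON	inherited	19	.	1	21	34923617	A	G	p.T694A	rs141608426	0.0034	D	D	1	DDG2P-monoallelic
PREX1	inherited	3	.	1	20	47309282	C	T	p.G322S	rs202212653	.	D	D	1	SFARI
PTPRT	inherited	10	.	1	20	40735430	G	C	p.T1129R	rs201830301	6.48E-05	D	D	1	SFARI
RIMS2	inherited	21	.	1	8	104897660	C	T	p.S86F	rs17854256	0.0062	D	P	1	DDG2P-monoallelic
KDM5A	inherited	4	.	1	12	430192	G	A	p.P837L	rs745469846	6.48E-05	D	D	1	DDG2P-monoallelic
DYNC1H1	de_novo	15	BAP	1	14	102509021	C	T	p.P4150L	.	.	D	D	1	DDG2P-monoallelic
KDM3A	de_novo	4	MAP	1	2	86716780	A	G	p.K1191E	.	.	D	D	1	DBDGD
ZBTB18	de_novo	22	.	1	1	244217437	G	C	p.V112L	.	0	D	D	1	DDG2P-monoallelic
TAF4	de_novo	4	MAP	1	20	60640497	C	G	p.A124P	.	.	D	P	2	AutDB
TAF4	de_novo	21	BAP	1	20	60640497	C	G	p.A124P	.	.	D	P	2	AutDB
CLOCK	inherited	22	BAP	0	4	56319253	C	G	p.E392Q	rs373421741	.	D	P	2	AutDB
JAG1	inherited	19	MAP	0	20	10621462	T	G	p.R1056S	rs146006022	0	D	P	2	AutDB
NCOR2	inherited	10	NAP	1	12	124832388	C	T	p.R1342H	rs36081651	0.0066	D	D	2	AutDB
STXBP5L	inherited	15	BAP	0	3	120952486	G	A	p.V379M	rs61996323	0.0084	D	D	2	AutDB
TNS3	inherited	15	BAP	0	7	47331594	G	A	p.T1296M	rs41280696	0.0086	D	D	2	AutDB
TTC28	inherited	14	NAP	0	22	28426233	G	A	p.R1352C	rs201500299	7.00E-04	D	D	2	AutDB
PTCH1	inherited	19	.	1	9	98242733	G	A	p.P295L	rs370755364	.	D	D	1	DBDGD
PHLPP1	de_novo	7	NAP	1	18	60506115	C	-	p.Y624fs	.	.	.	.	2	AutDB
CASKIN1	inherited	19	MAP	1	16	2231252	G	A	p.S706L	rs201599923	3.00E-04	D	D	3	SynaptomeDB
WDR7	inherited	10	NAP	1	18	54547385	C	G	p.A1139G	rs773660280	.	D	D	1	DDG2P-monoallelic
FAT3	inherited	14	MAP	1	11	92534043	G	T	p.V2622F	rs17615477	0.0054	D	D	3	SynaptomeDB
MACF1	inherited	3	NAP	1	1	39853641	G	T	p.A2981S	rs144760259	0.0052	D	D	1	DDG2P-monoallelic
MACF1	inherited	10	NAP	1	1	39763365	G	T	p.C815F	rs148207245	0.0069	D	P	1	DDG2P-monoallelic
PCDH1	inherited	15	BAP	0	5	141243507	G	A	p.R418C	rs143703336	6.48E-05	D	D	3	SynaptomeDB
VCAN	inherited	14	NAP	0	5	82786147	G	T	p.V101L	rs758097509	.	D	D	3	SynaptomeDB
PCLO	inherited	11	.	1	7	82584378	G	A	p.T1964M	rs148432464	0	D	P	3	SynaptomeDB
PSMD1	inherited	19	.	1	2	232010978	A	G	p.M675V	rs201118764	0	D	D	1	SFARI
TP53BP1	inherited	22	.	1	15	43714134	C	A	p.G1340V	rs570488146	.	D	P	3	SynaptomeDB
DGKI	de_novo	4	BAP	1	7	137531385	C	A	p.G75V	.	.	D	P	3	SynaptomeDB
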