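ko	kn_id	log2fc	description	pathway
K01885	46213	2.97	EARS, gltX; glutamyl-tRNA synthetase	Porphyrin & chlorophyll metabolism
K02492	12431	3.72	hemA; glutamyl-tRNA reductase	Porphyrin & chlorophyll metabolism
K01845	20139	1.64	hemL; glutamate-1-semialdehyde 2,1-aminomutase	Porphyrin & chlorophyll metabolism
K01698	9382	1.49	hemB, ALAD; porphobilinogen synthase	Porphyrin & chlorophyll metabolism
K01749	22375	1.43	hemC, HMBS; hydroxymethylbilane synthase	Porphyrin & chlorophyll metabolism
K00589	15072	-0.01	MET1; uroporphyrin-III C-methyltransferase	Porphyrin & chlorophyll metabolism
K01599	31220	3.08	hemE, UROD; uroporphyrinogen decarboxylase	Porphyrin & chlorophyll metabolism
K01599	51300	2.25	hemE, UROD; uroporphyrinogen decarboxylase	Porphyrin & chlorophyll metabolism
K00228	21674	2.17	CPOX, hemF; coproporphyrinogen III oxidase	Porphyrin & chlorophyll metabolism
K00231	43719	1.87	PPOX, hemY; oxygen-dependent protoporphyrinogen oxidase	Porphyrin & chlorophyll metabolism
K01772	15887	1.95	hemH, FECH; ferrochelatase	Porphyrin & chlorophyll metabolism
K01772	18091	0.18	hemH, FECH; ferrochelatase	Porphyrin & chlorophyll metabolism
K01772	19087	-0.72	hemH, FECH; ferrochelatase	Porphyrin & chlorophyll metabolism
K02257	21293	0.08	COX10; protoheme IX farnesyltransferase	Porphyrin & chlorophyll metabolism
K02259	1501	1.36	COX15; cytochrome c oxidase assembly protein subunit 15	Porphyrin & chlorophyll metabolism
K03403	43039	3.56	chlH, bchH; magnesium chelatase subunit H	Porphyrin & chlorophyll metabolism
K03403	15250	1.06	chlH, bchH; magnesium chelatase subunit H	Porphyrin & chlorophyll metabolism
K03404	17580	2.21	chlD, bchD; magnesium chelatase subunit D	Porphyrin & chlorophyll metabolism
K03428	10622	1.92	E2.1.1.11, chlM, bchM; magnesium-protoporphyrin O-methyltransferase	Porphyrin & chlorophyll metabolism
K00218	28240	0.38	E1.3.1.33, por; protochlorophyllide reductase	Porphyrin & chlorophyll metabolism
K00218	45156	0.42	E1.3.1.33, por; protochlorophyllide reductase	Porphyrin & chlorophyll metabolism
K04040	21874	1.16	chlG, bchG; chlorophyll synthase	Porphyrin & chlorophyll metabolism
K13606	65256	2.55	NOL, NYC1; chlorophyll(ide) b reductase	Porphyrin & chlorophyll metabolism
K10960	19661	1.82	chlP, bchP; geranylgeranyl reductase	Porphyrin & chlorophyll metabolism
K00510	28325	1.76	HMOX, hmuO, ho; heme oxygenase	Porphyrin & chlorophyll metabolism
K00510	67894	2.01	HMOX, hmuO, ho; heme oxygenase	Porphyrin & chlorophyll metabolism
K05370	8686	0.38	pebB; phycoerythrobilin:ferredoxin oxidoreductase	Porphyrin & chlorophyll metabolism
K01764	44227	1.23	E4.4.1.17; cytochrome c heme-lyase	Porphyrin & chlorophyll metabolism
K02291	46495	0.71	crtB; phytoene synthase	Carotenoid biosynthesis
K02291	41294	2.26	crtB; phytoene synthase	Carotenoid biosynthesis
K02293	16608	0.89	PDS, crtP; 15-cis-phytoene desaturase	Carotenoid biosynthesis
K02293	9496	2.23	PDS, crtP; 15-cis-phytoene desaturase	Carotenoid biosynthesis
K06443	39499	3.11	lcyB, crtL1, crtY; lycopene beta-cyclase	Carotenoid biosynthesis
K14606	6096	1.86	cruP; lycopene cyclase CruP	Carotenoid biosynthesis
K09837	28908	-3.68	LUT1, CYP97C1; carotene epsilon-monooxygenase	Carotenoid biosynthesis
K09838	40045	2.58	ZEP, ABA1; zeaxanthin epoxidase	Carotenoid biosynthesis
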