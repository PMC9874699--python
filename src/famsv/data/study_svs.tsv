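Chromosome	Start	Length	Type	Sample	Gene	Location	ConfirmedByIllumina
1	55334342	52	DEL	AP2	DHCR24	intron5	1
1	165317168	86	DEL	AP10	LMX1A	intron3	1
1	197323945	41	DEL	AP10	CRB1	intron6	1
2	71894430	32	DEL	AP4	DYSF	intron45	1
2	212771238	3918	DEL	AP4	ERBB4	intron3	1
2	213311309	36	DEL	AP3	ERBB4	intron1	1
2	240861056	40	DEL	AP10	NDUFA10	intron7	1
2	240865209	2291	DEL	AP13	NDUFA10	intron7	1
3	32172207	42	DEL	AP13	GPD1L	intron2	1
4	26290467	4918	DEL	AP3	RBPJ	intron1	1
4	55577813	76	DEL	AP3	KIT	intron7	1
5	497823	133	DEL	AP10	SLC9A3	intron1	1
5	35083885	51	DEL	AP3	PRLR	intron4	1
5	35734503	38	DEL	AP3	SPEF2	intron21	1
5	138111845	193	DEL	AP4	CTNNA1	intron1	1
5	148385841	99	DEL	AP3	SH3TC2	intron16	1
6	5738544	38	DEL	AP4	FARS2	intron6	1
6	16367939	44	DEL	AP11	ATXN1	intron7	1
6	162316509	220	DEL	AP12	PRKN	intron6	1
7	29303576	43	DEL	AP12	CHN2	intron2	1
7	29399723	38	DEL	AP10	CHN2	intron3	1
7	33348898	99	DEL	AP10	BBS9	intron9	1
7	117252063	42	DEL	AP3	CFTR	intron20	1
7	146883956	213	DEL	AP13	CNTNAP2	intron7	1
7	147044513	59	DEL	AP12	CNTNAP2	intron8	1
9	707446	571	DEL	AP12	KANK1	intron6	1
9	14498762	58	DEL	AP11	NFIB	intron1	1
10	271571	49	DEL	AP11	ZMYND11	intron3	1
10	26999004	3149	DEL	AP11	PDSS1	intron5	1
10	57161852	38	DEL	AP6	PCDH15	intron2	1
10	89676313	32	DEL	AP6	PTEN	intron2	1
11	67965907	35	DEL	AP11	KMT5B	intron1	1
11	102471852	311	DEL	AP9	MMP20	intron6	1
11	132995568	36	DEL	AP13	OPCML	intron1	1
11	133964510	61	DEL	AP2	JAM3	intron1	1
12	21737302	34	DEL	AP12	GYS2	intron1	1
12	57951986	269	DEL	AP3	KIF5A	intron1	1
13	39379287	4132	DEL	AP11	FREM2	intron6	1
14	67407796	59	DEL	AP11	GPHN	intron7	1
15	27137546	54	DEL	AP10	GABRA5	intron6	1
15	38835026	39	DEL	AP4	RASGRP1	intron2	1
15	59431438	34	DEL	AP6	MYO1E	intron26	1
15	76884596	12345	DEL	AP3	SCAPER	intron23	1
16	21718916	39	DEL	AP4	OTOA	intron12	1
16	23344422	54	DEL	AP6	SCNN1B	intron1	1
16	78653040	57	DEL	AP9	WWOX	intron7	1
17	11557383	320	DEL	AP6	DNAH9	intron14	1
18	10944496	33	DEL	AP11	PIEZO2	intron3	1
18	46816093	67	DEL	AP12	DYM	intron8	1
X	29821294	146	DEL	AP12	IL1RAPL1	intron6	1
X	76881497	62	DEL	AP1	ATRX	intron19	1
2	55877990	138	DEL	AP6	PNPT1	intron18	0
6	13231402	240	DEL	AP10	PHACTR1	intron11	0
6	162801507	34	DEL	AP4	PRKN	intron2	0
7	824878	77	DEL	AP11	DNAAF5	intron12	0
9	138649895	133	DEL	AP11	KCNT1	intron8	0
10	53313464	60	DEL	AP10	PRKG1	intron3	0
14	100810939	38	DEL	AP4	WARS1	intron7	0
15	27009296	48	DEL	AP9	GABRB3	intron3	0
2	15519545	320	INS	AP3	NBAS	exon30-intron30	0
2	38913368	51	INS	AP11	GALM	intron3	0
2	72478232	42	INS	AP3	EXOC6B	intron20	0
2	74259596	74	INS	AP10	TET3	intron3	0
2	179621874	434	INS	AP9	TTN	exon45-intron45	0
3	33085270	83	INS	AP11	GLB1	intron10	0
3	158195587	40	INS	AP13	RSRC1	intron6	0
4	9952515	35	INS	AP13	SLC2A9	intron5	0
4	42922732	345	INS	AP12	GRXCR1	intron1	0
4	151293907	336	INS	AP11	LRBA	intron47	0
5	35074614	38	INS	AP3	PRLR	intron4	0
5	78253753	355	INS	AP13	ARSB	intron3	0
6	129828230	357	INS	AP12	LAMA2	intron61	0
6	157397677	346	INS	AP13	ARID1B	intron6	0
6	169024302	32	INS	AP10	SMOC2	intron9	0
7	78997174	58	INS	AP6	MAGI2	intron1	0
7	87098256	40	INS	AP12	ABCB4	intron3	0
9	97387410	326	INS	AP3	FBP1	intron1	0
11	66008249	329	INS	AP3	PACS1	intron21	0
11	77043398	173	INS	AP9	PAK1	intron14	0
15	51978918	123	INS	AP3	SCG3	intron3	0
15	76723499	93	INS	AP4	SCAPER	intron27	0
16	78561889	36	INS	AP11	WWOX	intron7	0
18	59713725	331	INS	AP3	PIGN	intron29	0
20	33537824	49	INS	AP4	GSS	intron2	0
21	39004547	350	INS	AP6	KCNJ6	intron3	0
22	26997611	335	INS	AP11	CRYBB1	exon5-intron5	0
X	32897127	39	INS	AP10	DMD	intron2	0
X	76906706	44	INS	AP10	ATRX	intron15	0
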