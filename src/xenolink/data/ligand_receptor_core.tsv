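# Curated-style core ligand-receptor set (human symbols): a small starter
# database of well-established pairs for demonstration and testing.
ligand	receptor	source	pmid
HGF	MET	RTK signaling	1846706
EGF	EGFR	RTK signaling	6090945
TGFA	EGFR	RTK signaling	3907855
VEGFA	KDR	angiogenesis	1417831
VEGFA	FLT1	angiogenesis	1417831
VEGFA	NRP1	angiogenesis	9529250
VEGFB	FLT1	angiogenesis	8637916
VEGFC	FLT4	angiogenesis	8617204
PGF	FLT1	angiogenesis	1656371
ANGPT1	TEK	angiogenesis	8980223
ANGPT2	TEK	angiogenesis	9204896
SHH	PTCH1	hedgehog	8906787
IHH	PTCH1	hedgehog	8906787
IHH	PTCH2	hedgehog	9811851
DHH	PTCH1	hedgehog	8906787
SEMA3C	NRP1	axon guidance	9288753
SEMA3A	NRP1	axon guidance	9288753
SEMA4D	PLXNB1	axon guidance	10520995
EFNA1	EPHA2	ephrin	7973638
EFNB2	EPHB4	ephrin	8878483
EFNB1	EPHB2	ephrin	8878483
WNT7B	GPC3	wnt	18477453
WNT5A	FZD5	wnt	7792603
WNT3A	FZD1	wnt	9192896
SFRP1	FZD6	wnt	9096311
COL1A1	ITGA2	ECM-integrin	2649254
COL1A2	ITGA2	ECM-integrin	2649254
COL1A1	CD44	ECM-integrin	7680921
COL1A2	CD44	ECM-integrin	7680921
COL4A1	ITGA1	ECM-integrin	2649254
FN1	ITGA3	ECM-integrin	2940279
FN1	ITGB6	ECM-integrin	2940279
FN1	ITGA5	ECM-integrin	2940279
LAMB1	ITGA6	ECM-integrin	2175260
THBS1	CD36	ECM-integrin	1371676
IGF1	IGF1R	RTK signaling	2877871
IGF2	IGF1R	RTK signaling	2877871
INS	INSR	RTK signaling	4324173
TGFB1	TGFBR1	TGF-beta	1333888
TGFB1	TGFBR2	TGF-beta	1333888
TGFB1	ENG	TGF-beta	1326540
TGFB2	TGFBR2	TGF-beta	1333888
TGFB3	TGFBR2	TGF-beta	1333888
BMP2	BMPR1A	TGF-beta	7791754
BMP4	BMPR1B	TGF-beta	7791754
INHBA	ACVR2A	TGF-beta	1310899
FGF1	FGFR1	RTK signaling	1847668
FGF2	FGFR1	RTK signaling	1847668
FGF7	FGFR2	RTK signaling	1649563
FGF10	FGFR2	RTK signaling	9716527
PDGFA	PDGFRA	RTK signaling	2554309
PDGFB	PDGFRB	RTK signaling	2554309
KITLG	KIT	RTK signaling	1698126
CSF1	CSF1R	RTK signaling	3002577
FLT3LG	FLT3	RTK signaling	8396166
NGF	NTRK1	RTK signaling	1850821
BDNF	NTRK2	RTK signaling	1849459
JAG1	NOTCH1	notch	7697721
JAG2	NOTCH1	notch	7697721
DLL4	NOTCH1	notch	10950036
DLL1	NOTCH2	notch	7697721
CXCL12	CXCR4	chemokine	8752280
CCL2	CCR2	chemokine	8062384
CCL5	CCR5	chemokine	8699119
CX3CL1	CX3CR1	chemokine	9177350
IL6	IL6R	cytokine	3260069
IL1B	IL1R1	cytokine	2969618
IL10	IL10RA	cytokine	8386875
TNF	TNFRSF1A	cytokine	2158862
TNFSF10	TNFRSF10B	cytokine	9311998
FASLG	FAS	cytokine	8521815
LIF	LIFR	cytokine	1849460
OSM	OSMR	cytokine	8999038
GAS6	AXL	RTK signaling	7890768
NRG1	ERBB3	RTK signaling	8390038
NRG1	ERBB4	RTK signaling	8390038
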