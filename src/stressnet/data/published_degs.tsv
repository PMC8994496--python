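response_type	gene	regulator	qtl_traits
LT-specific DEG	ACOT11
LT-specific DEG	ADRB2		Tenderness score;Muscle compression;Saturated fatty acid content;Conjugated linoleic acid content
LT-specific DEG	ARL6IP2
LT-specific DEG	ATP1B1		Juiciness
LT-specific DEG	CDIPT		Tenderness score;Shear force
LT-specific DEG	CEBPB	TF
LT-specific DEG	CXCR6
LT-specific DEG	DFFB		Juiciness
LT-specific DEG	DLL4		Muscle pH;Marbling score
LT-specific DEG	DNAJB4		Shear force
LT-specific DEG	GLUL
LT-specific DEG	GPAM		Shear force
LT-specific DEG	HES1	TM
LT-specific DEG	HSPB1
LT-specific DEG	IDS
LT-specific DEG	IL16
LT-specific DEG	IMP3
LT-specific DEG	ITGAE
LT-specific DEG	LEAP2		Marbling score
LT-specific DEG	MED23	TM
LT-specific DEG	MUSK
LT-specific DEG	MYF6		Marbling score
LT-specific DEG	MYLC2
LT-specific DEG	MYOD1	TF
LT-specific DEG	NME6
LT-specific DEG	NOL6
LT-specific DEG	PDPR
LT-specific DEG	PIGM
LT-specific DEG	PITPNM2
LT-specific DEG	PLD1
LT-specific DEG	RAB3IL1		Tenderness score;Shear force;Juiciness;Marbling score
LT-specific DEG	SERPINE1
LT-specific DEG	SLC25A25
LT-specific DEG	SLC2A3
LT-specific DEG	THBS1
LT-specific DEG	TREM1
LT-specific DEG	XYLT2
LT-specific DEG	YWHAZ
ST-specific DEG	ADAMTS9
ST-specific DEG	ATL2
ST-specific DEG	CYP1A1
ST-specific DEG	HYAL2
ST-specific DEG	MYLK4
ST-specific DEG	PPP2B
ST-specific DEG	SLC2A8
ST-specific DEG	ZNF750	TM
Common DEG	ABRA
Common DEG	ATF3	TF
Common DEG	CEBPD	TF	Shear force;Marbling score
Common DEG	ETS2	TF
Common DEG	FOS	TF
Common DEG	GADD45A		Marbling score
Common DEG	GEM
Common DEG	HES6	TF
Common DEG	HEYL	TF
Common DEG	IFRD1
Common DEG	LCAT
Common DEG	LRP4
Common DEG	MYOG	TF
Common DEG	PDK4		Marbling score
Common DEG	PFKFB3
Common DEG	PGF
Common DEG	PMP22		Marbling score
Common DEG	RGS2
Common DEG	SDC4
Common DEG	SLC16A6
Common DEG	SMAD7	TF	Marbling score
Common DEG	SORBS1
Common DEG	SPOCK2
Common DEG	TUBB6
Common main regulator	AKT1
Common main regulator	EGF
Common main regulator	HIF1A	TF
Common main regulator	IFNG		Tenderness score
Common main regulator	IL1B		Marbling score
Common main regulator	INS
Common main regulator	MAPK1		Shear force
Common main regulator	MAPK14
Common main regulator	TGFB1
Common main regulator	TNF		Marbling score
Common main target	BCL2
Common main target	BGLAP
Common main target	CDKN1A
Common main target	COL3A1
Common main target	ERBB2		Muscle pH;Marbling score
Common main target	FN1
Common main target	ICAM1		Marbling score
Common main target	IL6		Marbling score
Common main target	MMP2
Common main target	PPARG	TF
Common main target	SELE		Juiciness
Common main target	SLC2A4
Common main target	TLR4		Shear force
Common main target	VEGFA
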