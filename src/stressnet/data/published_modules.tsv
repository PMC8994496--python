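muscle	module	p_value	occurrence	n_target_genes	genes
LT	ETSF_ETSF_01	0.076	16	15	IL16,SERPINE1,HES1,HSPBAP1,CDIPT,XYLT2,TUBB3,THBS1,MED23,GPAM,PIGM,CEBPD,HEYL,HES6,MYOD1
LT	SP1F_CAAT_02	0.040	10	9	NME6,SDC4,PDPR,HES6,PFKFB3,CDIPT,PMP22,THBS1,IFRD1
LT	CAAT_AP1F_01	0.035	8	8	SLC25A25,SERPINE1,NME6,IMP3,HSPBAP1,SLC2A3,THBS1,ATF3
LT	SP1F_EBOX_SP1F_01	0.024	8	7	DFFB,GLUL,PDK4,IMP3,PMP22,XYLT2,CEBPD
LT	CAAT_SP1F_01	0.088	5	5	SERPINE1,ATP1B1,GLUL,GEM,HES6
LT	GATA_GATA_GATA_01	0.037	5	3	NME6,SLC16A6,MED23
LT	YY1F_SRFF_02	0.016	3	3	SLC2A3,ATF3,FOS
LT	SORY_SORY_EGRF_01	0.061	3	3	MUSK,ATP1B1,RAB3IL1
LT	NFKB_NFKB_01	0.064	3	3	SLC25A25,GLUL,GEM
LT	HNF1_GATA_01	0.098	3	3	MED23,PLD1,ATP1B1
LT	KLFS_NR2F_KLFS_01	0.024	3	2	SERPINE1,TUBB3
LT	STAF_SP1F_01	0.026	2	2	GLUL,HEYL
LT	RXRF_EBOX_01	0.043	2	2	PDPR,RAB3IL1
LT	AP1F_SMAD_01	0.055	2	2	IL16,THBS1
LT	ETSF_AP1F_04	0.067	2	2	ACOT11,HSPBAP1
LT	CEBP_MYBL_03	0.076	2	2	ACOT11,HSPBAP1
LT	AARF_CEBP_01	0.091	2	2	ABRA,NME6
LT	BRNF_RXRF_02	0.066	4	1	DLL4
LT	NFKB_ETSF_01	0.007	2	1	DLL4
LT	SRFF_AP1F_01	0.047	1	1	FOS
LT	ETSF_SP1F_SMAD_01	0.062	1	1	HEYL
LT	YY1F_SRFF_01	0.076	1	1	FOS
LT	PAX8_NKXH_01	0.076	1	1	PMP22
LT	ETSF_SRFF_01	0.091	1	1	FOS
ST	SP1F_SP1F_06	0.002	30	14	PGF,GADD45A,SLC16A6,ADAMTS9,CYP1A1,SLC2A8,SDC4,PMP22,TUBB3,IFRD1,HYAL2,ATF3,HES6,HEYL
ST	NFKB_SP1F_03	0.002	12	8	SLC2A8,SDC4,MYLK4,PGF,LRP4,PMP22,HEYL,CEBPD
ST	SP1F_ETSF_04	0.087	8	8	ABRA,SDC4,PGF,LCAT,PMP22,CYP1A1,SMAD7,HES6
ST	SMAD_E2FF_01	0.088	12	7	SLC2A8,SDC4,IFRD1,PDK4,CEBPD,HES6,FOS
ST	SP1F_YY1F_01	0.044	10	7	PGF,ABRA,GEM,SDC4,SLC2A8,ATF3,HES6
ST	SP1F_CAAT_02	0.039	6	5	SDC4,PFKFB3,IFRD1,PMP22,HES6
ST	SP1F_EBOX_SP1F_01	0.085	4	4	MYLK4,PMP22,PDK4,CEBPD
ST	RUSH_EGRF_01	0.049	3	3	SDC4,GADD45A,SPOCK2
ST	IRFF_NFAT_01	0.084	3	3	MYLK4,ADAMTS9,IFRD1
ST	GATA_GATA_GATA_01	0.013	4	2	SLC16A6,ADAMTS9
ST	MYOD_MYOD_03	0.066	3	2	SPOCK2,HES6
ST	AP1F_ETSF_04	0.013	2	2	IFRD1,HYAL2
ST	YY1F_SRFF_02	0.028	2	2	ATF3,FOS
ST	ZFHX_ZFHX_NKXH_01	0.037	2	2	GADD45A,ADAMTS9
ST	SMAD_HIFF_01	0.032	2	1	PFKFB3
ST	SP1F_MZF1_01	0.035	2	1	PMP22
ST	ETSF_SP1F_SMAD_01	0.016	1	1	HEYL
ST	SRFF_AP1F_01	0.024	1	1	FOS
ST	YY1F_SRFF_01	0.039	1	1	FOS
ST	PAX8_NKXH_01	0.039	1	1	PMP22
ST	ETSF_SRFF_01	0.047	1	1	FOS
ST	MEF2_MYOD_01	0.054	1	1	SLC16A6
ST	KLFS_CREB_KLFS_01	0.070	1	1	SLC2A8
ST	CAAT_SREB_01	0.077	1	1	IFRD1
ST	GATA_HNF1_02	0.077	1	1	PDK4
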