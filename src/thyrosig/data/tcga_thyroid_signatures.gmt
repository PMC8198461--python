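MAPK_OUTPUT	TCGA-derived MAPK pathway transcriptional output signature (52 genes)	PHLDA1	SPRY1	SPRY2	SPRY4	SPRED1	SPRED2	DUSP4	DUSP5	DUSP6	ETV1	ETV4	ETV5	EPHA2	EPHA4	ELK3	FOSL1	CCND1	MYC	IER3	EGR1	TRIB2	LGALS3	MAFF	MAP2K3	PHLDA2	SLCO4A1	PLAUR	PPP1R15A	ZFP36	GLRX	LIF	SERPINB1	TRIB1	CDC42EP3	ITGA6	LZTS1	FXYD5	SEMA4B	KANK1	CSPG4	PROS1	RGS2	SHC4	GJA1	EREG	AREG	HBEGF	FGFBP1	EMP1	ANXA3	FOS	JUNB
THYROID_DIFFERENTIATION	TCGA-derived thyroid differentiation signature (16 genes)	SLC5A5	SLC5A8	SLC26A4	TG	TPO	TSHR	DIO1	DIO2	DUOX1	DUOX2	FOXE1	GLIS3	NKX2-1	PAX8	THRA	THRB
BRAF_RAS	TCGA-derived BRAF-RAS signaling signature (71 genes; up = RAS-like-high, down = BRAF-like-high)	TFF3|up	MT1G|up	MT1F|up	MT1X|up	FHL1|up	CRABP1|up	SLC26A7|up	ADH1B|up	CDH16|up	GPM6A|up	DPP6|up	FABP4|up	SORBS2|up	TCEAL2|up	KIT|up	SYT1|up	HGD|up	IPCEF1|up	MATN2|up	PKHD1L1|up	SLC4A4|up	PPARGC1A|up	CA4|up	CA12|up	OGDHL|up	TPD52L1|up	ITPR1|up	ANK2|up	RAP1GAP|up	TBC1D4|up	PDE8B|up	MPPED2|up	SELENBP1|up	GNAO1|up	FMO5|up	EPHX2|up	FN1|down	MET|down	TIMP1|down	SERPINA1|down	CLDN1|down	LAMB3|down	CITED1|down	PRSS23|down	CHI3L1|down	SLPI|down	SDC4|down	TACSTD2|down	KRT19|down	CD55|down	TNC|down	RUNX2|down	DCSTAMP|down	NGEF|down	PLXNC1|down	QPCT|down	ALDH1A3|down	ITGA3|down	MUC1|down	SPP1|down	PDZK1IP1|down	TMPRSS4|down	CDH3|down	GPRC5A|down	ABCC3|down	ENTPD1|down	SCEL|down	CAMK2N1|down	TGFA|down	NECTIN4|down	LRP4|down
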