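GO:0001	epithelium development	TG	TPO	TSHR	FOXE1	EPCAM	KRT8	CDH1
GO:0002	thyroid gland development	TG	TPO	TSHR	PAX8	NKX2-1	FOXE1	HHEX	GLIS3
GO:0003	lung development	SFTA3	SFTPB	NKX2-1	FGF10	FOXA2
GO:0004	cell proliferation	MKI67	PCNA	CCND1	MYC	IGF1
GO:0005	regulation of cell cycle	CCND1	CDK4	RB1	TP53
GO:0006	ion transmembrane transport	SLC26A4	SLC26A7	SLC5A5	KCNAB1	AQP4
GO:0007	anion transport	SLC26A4	SLC26A7	PDS
GO:0008	cAMP signaling	TSHR	GNAS	PDE8B	PDE10A	PRKX
GO:0009	growth factor signaling	IGF1	FGF10	FGF12	BMP7	BMP2	GDF10
GO:0010	hormone metabolic process	TG	TPO	DIO1	DIO2	IYD	DUOX2
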