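b_cells	Danaher et al. 2017 (J Immunother Cancer) marker-mean signature; reconstructed list	BLK	CD19	FCRL2	MS4A1	PNOC	SPIB	TCL1A	TNFRSF17
cd4_t_cells	CD4 T-cell marker set following the Davoli et al. addition; reconstructed list	CD4	IL7R	CD28	FOXP3	ICOS
cd45	Danaher et al. 2017 marker-mean signature; reconstructed list	PTPRC
cd8_t_cells	Danaher et al. 2017 marker-mean signature; reconstructed list	CD8A	CD8B
cytotoxic_cells	Danaher et al. 2017 marker-mean signature; reconstructed list	CTSW	GNLY	GZMA	GZMB	GZMH	KLRB1	KLRD1	KLRK1	NKG7	PRF1
dendritic_cells	Danaher et al. 2017 marker-mean signature; reconstructed list	CCL13	CD209	HSD11B1
exhausted_cd8	Danaher et al. 2017 marker-mean signature; reconstructed list	CD244	EOMES	LAG3	PTGER4
macrophages	Danaher et al. 2017 marker-mean signature; reconstructed list	CD163	CD68	CD84	MS4A4A
mast_cells	Danaher et al. 2017 marker-mean signature; reconstructed list	CPA3	HDC	MS4A2	TPSAB1	TPSB2
neutrophils	Danaher et al. 2017 marker-mean signature; reconstructed list	CEACAM3	CSF3R	FCAR	FCGR3B	FPR1	S100A12	SIGLEC5
nk_cd56dim_cells	Danaher et al. 2017 marker-mean signature; reconstructed list	IL21R	KIR2DL3	KIR3DL1	KIR3DL2
nk_cells	Danaher et al. 2017 marker-mean signature; reconstructed list	NCR1	XCL1	XCL2
t_cells	Danaher et al. 2017 marker-mean signature; reconstructed list	CD3D	CD3E	CD3G	CD6	SH2D1A	TRAT1
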