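kegg_pathway	pathway_name	dataset_id	subpathway	reported_p
hsa04340	Hedgehog signaling	GSE4107	PTCH1 (1.863) <- GLI2 (2.878) |- CSNK1G1 (0.587)	0.000035
hsa04340	Hedgehog signaling	GSE4107	WNT3 (3.147) <- GLI2 (2.878) |- CSNK1G1 (0.587)	0.000223
hsa04340	Hedgehog signaling	GSE12685	PTCH2 (0.938) <- GLI3 (0.682) |- GSK3B (1.513)	0.0015
hsa04360	Axon guidance	GSE1297	PAK3 (0.732) <- RAC1 (0.943) |- PLXNB3 (1.627) <- SEMA4C (1.283)	0.0008
hsa04360	Axon guidance	GSE12685	CFL1 (1.157) |- LIMK1 (0.896) <- PAK4 (0.871) <- RAC3 (0.892) <- PLXNA3 (0.954) <- FES (0.841)	0.0011
hsa04310	WNT signaling	GSE4107	JUN (4.179) <- TCF7L1 (2.735) <- CTNNB1 (2.562) |- GSK3B (0.735) |- DVL3 (1.608) <- FZD10 (6.256) <- WNT3 (3.147) <- PORCN (1.279)	0.000114
hsa04310	WNT signaling	GSE4107	JUN (4.179) <- TCF7L1 (2.735) <- CTNNB1 (2.562) |- GSK3B (0.735) |- DVL3 (1.608) <- APC2 (2.201) <- AXIN2 (2.307) <- CSNK1A1 (1.963)	0.00016
hsa05200	Pathways in cancer	GSE4107	MMP2 (3.031) <- JUN (4.179) <- MAPK1 (2.425) <- MAP2K1 (1.162) <- ARAF (4.631) <- HRAS (1.027) <- SOS1 (1.624) <- GRB2 (1.613) <- IGF1R (2.299) <- IGF1 (2.529)	0.000022
hsa04512	ECM-receptor interaction	GSE4107	SDC2 (3.091) <- TNC (9.557)	0.000026
hsa04512	ECM-receptor interaction	GSE4107	SDC2 (3.091) <- FN1 (5.594)	0.000125
hsa04512	ECM-receptor interaction	GSE1297	SDC3 (0.849) <- COL5A2 (0.162)	0.003
hsa04512	ECM-receptor interaction	GSE12685	SDC1 (0.865) <- COL3A1 (0.865)	0.0017
hsa04722	Neurotrophin signaling	GSE12685	BAD (1.279) |- AKT2 (0.856) <- PDK1 (0.943) <- PIK3CD (0.576) <- GAB1 (0.997) <- SHC2 (0.844) <- NTRK1 (0.945) <- NTF3 (0.784)	0.0008
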