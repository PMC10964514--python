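hypoxia_synthetic	synthetic placeholder hypoxia-response gene list (well-known HIF targets); swap in a curated collection for real analyses	VEGFA	CA9	SLC2A1	PGK1	LDHA	ENO1	ALDOA	BNIP3	PDK1	ADM	NDRG1	EGLN3	P4HA1	ANKRD37
glycolysis_synthetic	synthetic placeholder glycolysis gene list; swap in a curated collection for real analyses	HK2	PFKP	PFKL	ALDOA	GAPDH	PGK1	PGAM1	ENO1	ENO2	PKM	LDHA	SLC2A1	TPI1
oxidative_stress_synthetic	synthetic placeholder oxidative-stress / ROS-clearance gene list; swap in a curated collection for real analyses	SOD1	SOD2	CAT	GPX1	GPX4	TXN	TXNRD1	PRDX1	PRDX6	NQO1	HMOX1	GCLC	GCLM	GSR
p53_synthetic	synthetic placeholder p53-pathway gene list; swap in a curated collection for real analyses	CDKN1A	MDM2	BAX	GADD45A	SESN1	SESN2	TP53I3	RRM2B	ZMAT3	TIGAR	DDB2	PHLDA3
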