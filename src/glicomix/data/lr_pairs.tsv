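pair_id	ligand_genes	receptor_genes
SPP1_CD44	SPP1	CD44
SPP1_ITGAV_ITGB1	SPP1	ITGAV;ITGB1
FGF1_FGFR1	FGF1	FGFR1
FGF1_FGFR2	FGF1	FGFR2
FGF2_FGFR1	FGF2	FGFR1
FGF2_FGFR3	FGF2	FGFR3
PDGFA_PDGFRA	PDGFA	PDGFRA
PDGFA_PDGFRB	PDGFA	PDGFRB
PTN_PTPRZ1	PTN	PTPRZ1
PTN_SDC3	PTN	SDC3
MDK_PTPRZ1	MDK	PTPRZ1
VEGFA_FLT1	VEGFA	FLT1
HGF_MET	HGF	MET
TGFB1_TGFBR1_TGFBR2	TGFB1	TGFBR1;TGFBR2
CXCL12_CXCR4	CXCL12	CXCR4
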