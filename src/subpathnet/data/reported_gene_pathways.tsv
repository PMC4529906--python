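gene	pathways	crc_direction	ad_gse12685_direction	ad_gse1297_direction
PTPN6	hsa04662_B_cell_receptor_signaling_pathway;hsa04630_Jak-STAT_signaling_pathway;hsa05140_Leishmaniasis	Up	Down	Down
IRAK3	hsa04722_Neurotrophin_signaling_pathway	Up	Down	Down
FLT3	hsa05221_Acute_myeloid_leukemia	Up	Down	Down
DDIT3	hsa04010_MAPK_signaling_pathway	Up	Down	Down
FAS	hsa04115_p53_signaling_pathway;hsa04650_Natural_killer_cell_mediated_cytotoxicity	Up	Down	Down
IRF3	hsa04622_RIG-I-like_receptor_signaling_pathway;hsa04623_Cytosolic_DNA-sensing_pathway	Up	Down	Down
CCR6	hsa04060_Cytokine-cytokine_receptor_interaction;hsa04062_Chemokine_signaling_pathway	Up	Down	Down
CD28	hsa04660_T_cell_receptor_signaling_pathway;hsa05416_Viral_myocarditis	Up	Down	Down
FCER1G	hsa04650_Natural_killer_cell_mediated_cytotoxicity	Up	Down	Down
NGFR	hsa04722_Neurotrophin_signaling_pathway	Up	Down	Down
FN1	hsa04512_ECM-receptor_interaction	Up	Down	Down
BAD	hsa04510_Focal_adhesion;hsa05223_Non-small_cell_lung_cancer;hsa05210_Colorectal_cancer	Down	Up	Up
CD36	hsa03320_PPAR_signaling_pathway;hsa04512_ECM-receptor_interaction	Down	Up	Up
PPARD	hsa05221_Acute_myeloid_leukemia;hsa04310_Wnt_signaling_pathway	Down	Up	Up
ABL1	hsa04012_ErbB_signaling_pathway;hsa04722_Neurotrophin_signaling_pathway	Down	Up	Up
EGFR	hsa05214_Glioma;hsa04012_ErbB_signaling_pathway	Down	Up	Up
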