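gene,class_s1,class_s2
APC,WNT,WNT_destruction_complex
TP53,TP53_CELL_CYCLE,TP53_core
KRAS,RTK_RAS,RAS_GTPase
NRAS,RTK_RAS,RAS_GTPase
BRAF,RTK_RAS,MAPK_kinase
PIK3CA,PI3K,PI3K_catalytic
PTEN,PI3K,PI3K_phosphatase
SMAD4,TGF_BETA,SMAD_effector
SMAD2,TGF_BETA,SMAD_effector
FBXW7,TP53_CELL_CYCLE,ubiquitin_ligase
TCF7L2,WNT,WNT_transcription
CTNNB1,WNT,WNT_transcription
SOX9,WNT,WNT_transcription
ARID1A,CHROMATIN,SWI_SNF
RNF43,WNT,WNT_destruction_complex
TGFBR2,TGF_BETA,TGF_receptor
ACVR2A,TGF_BETA,TGF_receptor
BMPR1A,TGF_BETA,TGF_receptor
ATM,DNA_REPAIR,checkpoint_kinase
BRCA1,DNA_REPAIR,homologous_recombination
BRCA2,DNA_REPAIR,homologous_recombination
MLH1,DNA_REPAIR,mismatch_repair
MSH2,DNA_REPAIR,mismatch_repair
MSH3,DNA_REPAIR,mismatch_repair
MSH6,DNA_REPAIR,mismatch_repair
PMS2,DNA_REPAIR,mismatch_repair
POLE,DNA_REPAIR,polymerase_proofreading
POLD1,DNA_REPAIR,polymerase_proofreading
EGFR,RTK_RAS,receptor_tyrosine_kinase
ERBB2,RTK_RAS,receptor_tyrosine_kinase
ERBB3,RTK_RAS,receptor_tyrosine_kinase
MET,RTK_RAS,receptor_tyrosine_kinase
AKT1,PI3K,AKT_kinase
GNAS,OTHER,G_protein
AMER1,WNT,WNT_destruction_complex
KIT,RTK_RAS,receptor_tyrosine_kinase
STK11,PI3K,AMPK_axis
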