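gene,freq_msi,freq_mss
APC,0.25,0.75
TP53,0.20,0.65
KRAS,0.35,0.45
NRAS,0.03,0.05
BRAF,0.45,0.06
PIK3CA,0.35,0.18
PTEN,0.30,0.05
SMAD4,0.10,0.12
SMAD2,0.08,0.06
FBXW7,0.30,0.10
TCF7L2,0.25,0.08
CTNNB1,0.15,0.04
SOX9,0.20,0.07
ARID1A,0.40,0.08
RNF43,0.50,0.05
TGFBR2,0.55,0.03
ACVR2A,0.45,0.02
BMPR1A,0.12,0.02
ATM,0.25,0.08
BRCA1,0.08,0.03
BRCA2,0.18,0.04
MLH1,0.30,0.02
MSH2,0.15,0.02
MSH3,0.35,0.02
MSH6,0.25,0.03
PMS2,0.10,0.02
POLE,0.10,0.03
POLD1,0.08,0.02
EGFR,0.12,0.05
ERBB2,0.15,0.04
ERBB3,0.18,0.05
MET,0.08,0.03
AKT1,0.06,0.02
GNAS,0.10,0.04
AMER1,0.15,0.06
KIT,0.07,0.03
STK11,0.05,0.02
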