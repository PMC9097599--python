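# 84-gene lung-cancer panel (synthetic stand-in).
# The shared capture design of the three commercial panels used for the
# cohort is not public; this list of well-known lung-cancer genes is a
# placeholder of the same size and is meant to be replaced by the user's
# own one-gene-per-line panel file.
EGFR
ALK
ERBB2
ERBB3
ERBB4
KRAS
NRAS
HRAS
BRAF
RAF1
MET
ROS1
RET
NTRK1
NTRK2
NTRK3
TP53
STK11
KEAP1
PIK3CA
PIK3R1
PTEN
RB1
CDKN2A
CDKN2B
SMARCA4
ARID1A
ARID2
NF1
NF2
MAP2K1
MAP2K2
AKT1
AKT2
MTOR
TSC1
TSC2
FGFR1
FGFR2
FGFR3
FGFR4
KIT
PDGFRA
PDGFRB
KDR
FLT3
JAK1
JAK2
JAK3
STAT3
SMAD4
APC
CTNNB1
NOTCH1
NOTCH2
FBXW7
EZH2
SETD2
KMT2A
KMT2C
KMT2D
CREBBP
EP300
BRCA1
BRCA2
ATM
ATR
CHEK1
CHEK2
PALB2
RAD51
MLH1
MSH2
MSH6
PMS2
POLE
POLD1
DDR2
MYC
CCND1
CCNE1
CDK4
CDK6
MDM2
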