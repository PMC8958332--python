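TESPA1
CCDC88B
PIK3CD
BTN3A1
AP3D1
IKBKB
RAB29
ZBTB7B
SART1
NCK2
JAK2
GRAP2
SASH3
SOD1
PNP
ABL1
IFNG
IL2RA
CD4
TFRC
ANXA1
CD3D
HLA-A
HLA-DPB1
ICAM1
JUN
CD5
LCK
CD2
CTSL
CD3E
LGALS1
HMGB1
CD7
CD3G
PRKAR1A
CD28
HSPD1
SRF
HLA-E
LCP1
RAC2
VAV1
SPN
CREB1
NCK1
CTLA4
IL7R
CTPS1
LGALS3
EGR1
LAG3
PLCG1
NFKB1
TNFRSF1B
ITGAL
BCL3
RPS3
GATA3
MSN
CD27
DPP4
PIK3R1
ITPKB
MAPK1
PTPN6
CD40LG
SLC7A1
CORO1A
AKT1
PRDX2
TNFSF8
PTGER4
MYH9
MAP2K2
TGFBR2
DDOST
PSMB10
CSK
STAT5A
PIK3CA
WAS
ZAP70
TNFRSF4
MAP2K4
ZFP36L2
CD151
PIK3CG
RAB27A
AIF1
NCKAP1L
B2M
RPS6
GRB2
RAC1
ADAM8
SMAD3
EFNB1
RELB
MAP2K1
PTPN11
ZFP36L1
ITK
NFATC3
LCP2
FADD
PAK2
MAP3K1
IL18R1
TCIRG1
RUNX3
CBFB
FLOT2
FGL2
STAT4
CASP8
PDK1
RHOH
BATF
CAMK4
ZC3H12A
TNFAIP8L2
IL27RA
APBB1IP
METTL3
RASAL3
ZFPM1
ZC3H8
RSAD2
DOCK2
KAT2A
GLMN
DNAJA3
MAP3K3
NDFIP1
FANCD2
TWSG1
AZI2
VSIR
NHEJ1
CD274
CHD7
STOML2
TBX21
SIT1
RIPOR2
RIPK3
SELENOK
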