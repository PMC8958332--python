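IKBKB
JAK2
IFNG
ANXA1
JUN
LCK
HMGB1
VAV1
SPN
CREB1
PLCG1
NFKB1
BCL3
GATA3
PIK3R1
MAPK1
PTPN6
MAP2K2
STAT5A
ZAP70
MAP2K4
RELB
MAP2K1
ITK
NFATC3
LCP2
MAP3K1
IL18R1
STAT4
PDK1
CAMK4
IL27RA
MAP3K3
TBX21
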