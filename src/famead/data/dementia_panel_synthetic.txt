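# Synthetic stand-in for a comprehensive dementia gene panel.
# Assembled from well-established AD / FTD-ALS / prion / parkinsonism genes;
# the original study's full panel is not publicly printed. One symbol per line.
APP
PSEN1
PSEN2
APOE
SORL1
TREM2
ABCA7
ABI3
ADAM10
AKAP9
BIN1
CLU
CR1
FERMT2
MADD
PICALM
PLCG2
PLD3
UNC5C
GRN
MAPT
C9orf72
TBK1
VCP
CHMP2B
CHCHD10
SQSTM1
TARDBP
FUS
UBQLN2
OPTN
CSF1R
NOTCH3
ITM2B
TYROBP
PRNP
SNCA
LRRK2
GBA
PARK7
PINK1
PRKN
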