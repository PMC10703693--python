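gene
ASXL1
ASXL2
ATM
BCOR
BCORL1
BRAF
BRCC3
CBL
CBLB
CEBPA
CREBBP
CSF1R
CSF3R
CTCF
CUX1
DDX41
DNMT3A
EP300
ETV6
EZH2
FLT3
GATA2
GATA3
GNA13
GNAS
GNB1
IDH1
IDH2
IKZF1
JAK1
JAK2
JAK3
KDM6A
KIT
KMT2A
KMT2D
KRAS
LUC7L2
MGA
MPL
MYD88
NF1
NPM1
NRAS
PDS5B
PHF6
PIGA
PPM1D
PRPF8
PTEN
PTPN11
RAD21
RIT1
RUNX1
SETBP1
SETD2
SETDB1
SF1
SF3A1
SF3B1
SH2B3
SMC1A
SMC3
SRSF2
STAG2
STAT3
SUZ12
TET2
TP53
U2AF1
WT1
ZBTB33
ZRSR2
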