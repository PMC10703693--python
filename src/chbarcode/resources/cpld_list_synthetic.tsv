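gene	hgvsp
DNMT3A	R882H
DNMT3A	R882C
DNMT3A	R736H
JAK2	V617F
TP53	R175H
TP53	R273H
SF3B1	K700E
SF3B1	K666N
SRSF2	P95H
SRSF2	P95L
GNB1	K57E
GNAS	R201C
MYD88	L252P
IDH2	R140Q
KRAS	G12D
NRAS	G12D
CBL	Y371H
MPL	W515L
KIT	D816V
PPM1D	R552*
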