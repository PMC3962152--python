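protein
AKT1
APC
APP
AR
AXIN1
CCND1
CDC42
CDH1
CDH2
CDH5
CREBBP
CTNNA1
CTNNB1
CTNND1
DLL1
DVL1
EGFR
EP300
ESR1
GSK3A
GSK3B
HDAC1
HNF4A
JUN
JUP
KAT2B
LEF1
MYC
MYOD1
NFKB1
NOTCH1
NOTCH2
NOTCH3
PSEN1
RAC1
RBPJ
SMAD2
SMAD3
SMAD4
SRC
UBC
VEGFA
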