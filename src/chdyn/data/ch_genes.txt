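# Genes recurrently mutated in clonal hematopoiesis (editable default panel).
DNMT3A
TET2
ASXL1
PPM1D
TP53
ATM
CHEK2
JAK2
SF3B1
SRSF2
U2AF1
ZRSR2
GNB1
GNAS
IDH1
IDH2
CBL
KRAS
NRAS
RUNX1
STAG2
BCOR
SH2B3
MPL
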