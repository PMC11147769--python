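# Homologous-recombination pathway panel (editable stand-in default;
# replace with a study-specific list via --genes / config).
BRCA1
BRCA2
PALB2
BARD1
BRIP1
RAD51
RAD51B
RAD51C
RAD51D
RAD54L
RAD50
MRE11
NBN
ATR
CHEK1
FANCA
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCI
FANCL
FANCM
XRCC2
XRCC3
EME1
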