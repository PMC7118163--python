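# Proposed ovarian carcinoma predisposition genes (carriers retained in
# the discovery cohort).
PALB2
FANCM
ATM
TP53
CHEK2
BARD1
STK11
CDH1
PTEN
FANCC
RECQL
BLM
NF1
MRE11A
NBN
RAD50
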