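# Known ovarian carcinoma predisposition genes (solved-case tier).
# BRCA1/2 included as a sanity check: the cohort is pre-screened, so no
# findings are expected in them.
BRCA1
BRCA2
MLH1
MSH2
MSH6
PMS2
BRIP1
RAD51C
RAD51D
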