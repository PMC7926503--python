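gene	direction
CLDN3	down
CLDN4	down
CLDN7	down
CDH1	down
OCLN	down
VIM	up
SNAI1	up
SNAI2	up
TWIST1	up
TWIST2	up
ZEB1	up
ZEB2	up
CD44	up
CD24	down
EPCAM	down
MUC1	down
ALDH1A1	up
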