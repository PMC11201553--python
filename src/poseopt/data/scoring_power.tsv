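system	glide	anicgbs
5-HT2AR	0.23	0.20
A2AR	0.29	0.02
CB1	0.19	0.23
CFX	0.10	0.04
D2R	0.11	0.12
ERK2	0.60	0.54
ER	0.60	0.60
M1R	0.21	0.31
muOR	0.16	0.16
rRNA	0.24	0.85
VEGFR2	0.48	0.45
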