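system	glide	anicgbs
5-HT2AR	0.21	0.19
A2AR	0.30	0.07
CB1	0.21	0.25
CFX	0.29	0.06
D2R	0.10	0.14
ERK2	0.57	0.36
ER	0.65	0.61
M1R	0.30	0.47
muOR	0.14	0.16
rRNA	0.14	0.69
VEGFR2	0.47	0.46
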