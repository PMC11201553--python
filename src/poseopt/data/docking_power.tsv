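system	method	top1	top3	top5	top10
5-HT2AR	anicgbs	2.96	0.92	0.92	0.92
A2AR	anicgbs	1.43	1.10	1.10	1.10
CB1	anicgbs	0.88	0.69	0.69	0.69
CFX	anicgbs	8.69	8.48	1.62	1.12
D2R	anicgbs	5.34	0.38	0.38	0.38
ERK2	anicgbs	0.88	0.52	0.52	0.52
ER	anicgbs	1.46	1.15	1.13	0.81
M1R	anicgbs	0.89	0.34	0.34	0.34
muOR	anicgbs	1.20	1.08	1.08	1.08
rRNA	anicgbs	5.92	5.83	5.82	5.82
VEGFR2	anicgbs	0.96	0.63	0.63	0.63
3VQG	anicgbs	1.21	1.12	1.12	1.12
3BS4	anicgbs	1.33	1.28	1.28	1.28
1N7F	anicgbs	2.29	2.29	2.29	2.29
3IDG	anicgbs	6.82	6.82	4.46	4.11
2HPL	anicgbs	4.30	4.23	4.23	4.23
4Q6H	anicgbs	5.93	4.78	4.78	4.78
4V3I	anicgbs	6.72	6.72	6.72	6.72
3CH8	anicgbs	12.99	11.97	7.17	5.69
2XFX	anicgbs	14.52	7.44	7.44	7.44
4N7H	anicgbs	11.02	7.77	7.77	7.77
4J8S	anicgbs	8.83	8.83	8.29	8.00
4EIK	anicgbs	12.50	8.47	8.47	8.47
5-HT2AR	glide	2.98	2.25	1.56	1.10
A2AR	glide	1.85	1.85	0.68	0.68
CB1	glide	0.82	0.74	0.74	0.74
CFX	glide	8.55	8.27	1.47	1.07
D2R	glide	1.98	0.59	0.59	0.59
ERK2	glide	0.47	0.47	0.47	0.47
ER	glide	1.12	1.12	1.12	0.72
M1R	glide	1.15	0.22	0.22	0.22
muOR	glide	1.08	1.07	0.99	0.99
rRNA	glide	6.11	5.96	5.96	5.93
VEGFR2	glide	0.52	0.52	0.52	0.52
3VQG	glide	1.14	1.13	1.13	1.13
3BS4	glide	1.31	1.31	1.31	1.31
1N7F	glide	2.15	2.15	2.15	2.15
3IDG	glide	6.97	4.16	4.16	4.16
2HPL	glide	4.27	4.21	4.21	4.21
4Q6H	glide	6.05	4.63	4.60	4.60
4V3I	glide	8.08	8.08	8.08	6.81
3CH8	glide	7.07	7.07	7.07	5.76
2XFX	glide	10.38	10.38	7.63	7.63
4N7H	glide	9.99	9.64	7.82	7.82
4J8S	glide	8.71	8.71	8.71	8.34
4EIK	glide	8.53	8.53	8.53	8.53
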