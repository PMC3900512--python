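codon	aa	count	rscu
UUU	F	163	1.33
UUC	F	82	0.67
UUA	L	193	2.31
UUG	L	48	0.57
CUU	L	99	1.18
CUC	L	43	0.51
CUA	L	94	1.12
CUG	L	25	0.30
AUU	I	200	1.49
AUC	I	68	0.51
AUA	M	135	1.56
AUG	M	38	0.44
GUU	V	65	1.68
GUC	V	22	0.57
GUA	V	54	1.39
GUG	V	14	0.36
UCU	S	67	1.76
UCC	S	51	1.34
UCA	S	77	2.02
UCG	S	13	0.34
CCU	P	85	1.50
CCC	P	68	1.20
CCA	P	60	1.06
CCG	P	14	0.25
ACU	T	89	1.51
ACC	T	49	0.83
ACA	T	87	1.48
ACG	T	10	0.17
GCU	A	48	1.28
GCC	A	45	1.20
GCA	A	50	1.33
GCG	A	7	0.19
UAU	Y	99	1.38
UAC	Y	44	0.62
UAA	*	98	1.56
UAG	*	28	0.44
CAU	H	67	1.28
CAC	H	38	0.72
CAA	Q	89	1.59
CAG	Q	23	0.41
AAU	N	202	1.47
AAC	N	72	0.53
AAA	K	210	1.65
AAG	K	44	0.35
GAU	D	54	1.57
GAC	D	15	0.43
GAA	E	67	1.58
GAG	E	18	0.42
UGU	C	10	0.80
UGC	C	15	1.20
UGA	W	74	1.68
UGG	W	14	0.32
CGU	R	14	1.06
CGC	R	9	0.68
CGA	R	24	1.81
CGG	R	6	0.45
AGU	S	28	0.73
AGC	S	19	0.50
AGA	S	29	0.76
AGG	S	21	0.55
GGU	G	29	0.79
GGC	G	5	0.14
GGA	G	81	2.20
GGG	G	32	0.87
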