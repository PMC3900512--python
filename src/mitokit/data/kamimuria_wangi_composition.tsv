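region	genome	A	T	G	C	AT	GC	at_skew	gc_skew
Whole mtDNA	Kw	35.6	34.0	11.5	18.9	69.6	30.4	0.02	-0.24
Whole mtDNA	Pp	36.6	34.0	11.5	17.9	70.6	29.4	0.04	-0.22
Protein coding genes	Kw	34.7	33.3	12.2	19.8	68.0	32.0	0.02	-0.23
Protein coding genes	Pp	36.2	34.3	11.6	17.9	70.5	29.5	0.03	-0.21
1st codon position	Kw	34.8	28.7	16.2	20.3	63.5	36.5	0.10	-0.11
1st codon position	Pp	37.0	34.0	13.0	16.2	71.0	29.2	0.04	-0.11
2nd codon position	Kw	31.2	35.9	11.0	21.9	67.1	32.9	-0.07	-0.33
2nd codon position	Pp	32.7	33.0	14.1	20.1	65.7	34.2	-0.01	-0.18
3rd codon position	Kw	38.0	35.3	9.5	17.2	73.3	26.7	0.04	-0.29
3rd codon position	Pp	38.9	36.0	7.8	17.4	74.9	25.2	0.04	-0.38
tRNA genes	Kw	36.8	35.6	12.1	15.4	72.4	27.5	0.02	-0.12
tRNA genes	Pp	35.8	34.3	13.2	16.8	70.1	30.0	0.02	-0.12
lrRNA	Kw	38.5	34.6	8.8	18.1	73.1	26.9	0.05	-0.35
lrRNA	Pp	39.8	34.2	8.1	17.9	74.0	26.0	0.08	-0.37
srRNA	Kw	37.0	30.6	11.0	21.5	67.6	32.5	0.09	-0.32
srRNA	Pp	37.3	31.3	11.6	19.8	68.6	31.4	0.09	-0.26
A+T-rich region	Kw	38.8	39.4	7.6	14.2	78.2	21.8	-0.01	-0.30
A+T-rich region	Pp	43.9	37.4	6.4	12.3	81.3	18.7	0.08	-0.32
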