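H	VN:Z:1.0
S	A	ACGT
S	B	CCAA
S	C	GGTC
S	D	TTAG
L	A	+	B	+	0M
L	C	+	D	+	0M
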