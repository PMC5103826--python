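H	VN:Z:1.0
S	A	ACGT	RC:i:400
S	B	CCAA	RC:i:380
S	C	GGTC	RC:i:420
S	D	TTAG	RC:i:390
S	E	AACG	RC:i:410
L	A	+	B	+	0M
L	B	+	C	+	0M
L	C	+	D	+	0M
L	D	+	E	+	0M
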