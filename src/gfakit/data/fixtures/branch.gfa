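H	VN:Z:1.0
S	s	ACGTACGTAC	RC:i:200	cn:i:2
S	u	AAAACCCCGG	RC:i:100	cn:i:1
S	a	TTTTGGGGCA	RC:i:100	cn:i:1
S	b	CCCCAAAATG	RC:i:100	cn:i:1
S	c	GGGGTTTTAC	RC:i:100	cn:i:1
L	u	+	s	+	0M
L	s	+	a	+	0M
L	s	+	b	+	0M
L	s	+	c	+	0M
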