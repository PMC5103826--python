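H	VN:Z:1.0
S	A	ACGTAC	RC:i:300
S	b1	TTGCAA	RC:i:40
S	b2	TTGGAA	RC:i:300
S	C	GGTCCA	RC:i:310
L	A	+	b1	+	0M
L	A	+	b2	+	0M
L	b1	+	C	+	0M
L	b2	+	C	+	0M
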