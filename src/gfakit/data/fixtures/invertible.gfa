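H	VN:Z:1.0
S	A	ACCGGT
S	X	ACGTCGT
S	C	TGGCCA
L	A	+	X	+	0M
L	A	+	X	-	0M
L	X	+	C	+	0M
L	X	-	C	+	0M
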