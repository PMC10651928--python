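A	a1
A	a2
A	a3
A	a4
A	a5
B	b1
B	b2
B	b3
B	b4
B	b5
C	c1
C	c2
C	c3
C	c4
C	c5
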