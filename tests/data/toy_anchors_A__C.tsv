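a1	c1	blk1
a2	c2	blk1
a4	c4	blk2
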