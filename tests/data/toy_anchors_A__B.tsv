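a1	b1	blk1
a2	b2	blk1
a3	b3	blk1
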