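b4	c3	blk1
b5	c4	blk1
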