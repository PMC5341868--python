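marker	a	b	c	d
B7-H3	28	21	9	20
B7-H4	30	20	7	21
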