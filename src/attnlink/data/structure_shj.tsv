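stimulus	D1	D2	D3	I	II	VI	role
1	0	0	0	A	A	A	both
2	0	0	1	A	B	B	both
3	0	1	0	A	B	B	both
4	0	1	1	A	A	A	both
5	1	0	0	B	A	B	both
6	1	0	1	B	B	A	both
7	1	1	0	B	B	A	both
8	1	1	1	B	A	B	both
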