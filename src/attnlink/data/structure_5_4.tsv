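stimulus	D1	D2	D3	D4	5_4	role
A1	1	0	0	0	A	training
A2	1	0	1	0	A	training
A3	0	1	0	0	A	training
A4	0	0	1	0	A	training
A5	0	0	0	1	A	training
B1	1	1	0	0	B	training
B2	1	0	0	1	B	training
B3	0	1	1	1	B	training
B4	1	1	1	1	B	training
T1	0	1	1	0	-	transfer
T2	1	1	1	0	-	transfer
T3	0	0	0	0	-	transfer
T4	1	1	0	1	-	transfer
T5	0	1	0	1	-	transfer
T6	0	0	1	1	-	transfer
T7	1	0	1	1	-	transfer
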