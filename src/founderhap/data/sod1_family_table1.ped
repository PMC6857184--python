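FAM1	I:1	0	0	1	2
FAM1	I:2	0	0	2	1
FAM1	II:1	I:1	I:2	1	2
FAM1	II:3	I:1	I:2	2	1
FAM1	II:4	I:1	I:2	2	1
FAM1	II:5	I:1	I:2	1	2
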