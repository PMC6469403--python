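# dmd-10/11 RNAi vs control injections: per-mother progeny counts by sex
mother_id	condition	males	females	hermaphrodites
1	RNAi	21	57	61
2	RNAi	12	90	76
3	RNAi	7	82	185
4	RNAi	18	101	227
5	RNAi	13	94	52
6	RNAi	2	95	89
7	RNAi	4	55	88
8	RNAi	2	53	64
9	Control	3	33	107
10	Control	4	43	254
11	Control	12	44	329
12	Control	1	4	20
13	Control	0	26	40
14	Control	15	53	158
15	Control	3	25	70
16	Control	12	75	190
17	Control	8	69	142
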