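family	n_informative
1	11
2	3
3	22
4	8
5	67
6	10
7	70
8	5
9	27
10	19
11	71
12	4
13	61
14	0
15	31
16	1
17	27
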