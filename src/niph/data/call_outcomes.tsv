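family	replicate	tp	fn	tn	fp	transmitted
1	275_a	7	4	0	0	path
1	275_b	9	2	0	0	path
2	311_a	1	0	2	0	wt
2	311_b	1	0	2	0	wt
3	322_a	0	0	22	0	path
3	322_b	0	0	22	0	path
4	323_a	8	0	0	0	wt
4	323_b	8	0	0	0	wt
5	306	51	16	0	0	wt
6	303	10	0	0	0	wt
7	296	0	0	70	0	path
8	274	1	0	4	0	wt
9	273	0	0	27	0	path
10	350	13	0	5	1	path
11	352	1	0	68	2	path
12	253	4	0	0	0	wt
13	337	31	0	30	0	path
14	360	0	0	0	0	none
15	361	29	1	1	0	wt
16	371	0	0	1	0	wt
17	374	24	2	1	0	path
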