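family	replicate	max_error	sd_error	cutoff
1	275_a	1.404	0.237	1.641
1	275_b	1.69	0.196	1.886
2	311_a	0.919	0.194	1.113
2	311_b	0.533	0.118	0.651
3	322_a	0.463	0.116	0.579
3	322_b	0.533	0.138	0.671
4	323_a	0.688	0.129	0.817
4	323_b	0.737	0.165	0.902
5	306	1.299	0.223	1.522
6	303	0.619	0.122	0.741
7	296	1.434	0.243	1.677
8	274	1.655	0.33	1.985
9	273	0.465	0.118	0.583
10	350	0.228	0.063	0.291
11	352	0.302	0.073	0.376
12	253	0.870	0.156	1.027
13	337	0.462	0.090	0.553
14	360	0.400	0.099	0.499
15	361	0.736	0.230	0.967
16	371	0.843	0.155	0.998
17	374	0.932	0.214	1.147
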