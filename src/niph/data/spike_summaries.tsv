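sample	expected_percent	n_sites	mean	sd	median	mean_minus_1sd	mean_plus_1sd
Spike 1.25%	1.25	67	0.85	0.96	0.28	-0.12	1.81
Spike 2.5%	2.5	67	1.97	1.85	1.92	0.13	3.82
Spike 5%	5.0	67	2.95	1.63	2.58	1.32	4.58
Spike 10%	10.0	67	8.55	2.87	8.25	5.67	11.42
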