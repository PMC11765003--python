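family	member	sample_id	source	hgvs_genotype
1	mother	50289	WBC	NM_000518.5:c.[92+1G>A];[92+1=]
1	father	50290	WBC	NM_000518.5:c.[316-106C>G];[316-106=]
1	fetus	3871/50353	CVS	NM_000518.5:c.[92+1G>A];[316-106C>G]
2	mother	50321	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
2	father	50322	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
2	fetus	4123/53660	CVS	NM_000518.5:c.[=];[=]
2	mother_of_mother	50323	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
2	father_of_mother	50324	WBC	NM_000518.5:c.[=];[=]
2	mother_of_father	50325	WBC	NM_000518.5:c.[=];[=]
2	father_of_father	50326	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
3	mother	52205	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
3	father	52206	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
3	fetus	4142/53887	CVS	NM_000518.5:c.[93-21G>A];[93-21G>A]
4	mother	53973	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
4	father	41110	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
4	fetus	4147/53929	CVS	NM_000518.5:c.[93-21G>A];[93-21=]
5	mother	53212	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
5	father	53213	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
5	fetus	4100/53323	CVS	NM_000518.5:c.[93-21G>A];[93-21=]
6	mother	53195	WBC	NM_000518.5:c.[118C>T];[118=]
6	father	53196	WBC	NM_000518.5:c.[118C>T];[118=]
6	fetus	4095/53252	CVS	NM_000518.5:c.[118C>T];[118=]
7	mother	52952	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
7	father	52953	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
7	fetus	4081/52990	CVS	NM_000518.5:c.[93-21G>A];[93-21=]
8	mother	50040	WBC	NM_000518.5:c.[92+1G>A];[92+1=]
8	father	50041	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
8	fetus	3854/50140	CVS	NM_000518.5:c.[=];[=]
9	mother	49899	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
9	father	49900	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
9	fetus	3836/49924	CVS	NM_000518.5:c.[93-21G>A];[93-21=]
10	mother	57203	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
10	father	57204	WBC	NM_000518.5:c.[92+1G>A];[92+1=]
10	fetus	57219/4359	CVS	NM_000518.5:c.[92+1G>A];[92+1=]
11	mother	57262	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
11	father	57263	WBC	NM_000518.5:c.[92+1G>A];[92+1=]
11	fetus	57261/4369	CVS	NM_000518.5:c.[92+1G>A];[92+1=]
12	mother	49166	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
12	father	49167	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
12	fetus	49283/3789	CVS	NM_000518.5:c.[93-21G>A];[93-21=]
13	mother	56423	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
13	father	12506	WBC	NM_000518.5:c.[92+6T>C];[-137C>G]
13	fetus	56389/4301	CVS	NM_000518.5:c.[93-21G>A];[92+6T>C]
14	mother	50542	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
14	father	50543	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
14	fetus	58209/4419	CVS	NM_000518.5:c.[93-21G>A];[93-21=]
15	mother	51468	WBC	NM_000518.5:c.[118C>T];[118=]
15	father	51469	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
15	fetus	58210/4420	CVS	NM_000518.5:c.[118C>T];[118=]
16	mother	59244	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
16	father	59245	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
16	fetus	59283/4485	CVS	NM_000518.5:c.[93-21G>A];[93-21=]
16	mother_of_mother	59246	WBC	NM_000518.5:c.[=];[=]
16	father_of_mother	59247	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
16	mother_of_father	59248	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
16	father_of_father	59249	WBC	NM_000518.5:c.[=];[=]
17	mother	58552	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
17	father	58553	WBC	NM_000518.5:c.[92+6T>C];[92+6=]
17	fetus	59408/4492	CVS	NM_000518.5:c.[93-21G>A];[92+6T>C]
17	mother_of_mother	59344	WBC	NM_000518.5:c.[=];[=]
17	father_of_mother	59345	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
17	mother_of_father	59346	WBC	NM_000518.5:c.[93-21G>A];[93-21=]
17	father_of_father	59347	WBC	NM_000518.5:c.[92+6T>C];[92+6=]
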