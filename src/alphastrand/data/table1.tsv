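system_id	pdb_id	variant	counter_ion	temperature_K	ph	run_ns
1	1IYT	WT	3 Na+	310	NpH	50
2	1Z0Q	WT	3 Na+	310	NpH	50
3	2NAO	WT	3 Na+	310	NpH	50
4	1IYT	WT	3 Na+	498	NpH	50
5	1Z0Q	WT	3 Na+	498	NpH	50
6	2NAO	WT	3 Na+	498	NpH	50
7	1IYT	WT	6 Cl-	310	LpH	50
8	1Z0Q	WT	6 Cl-	310	LpH	50
9	2NAO	WT	6 Cl-	310	LpH	50
10	1IYT	WT	6 Cl-	498	LpH	50
11	1Z0Q	WT	6 Cl-	498	LpH	50
12	2NAO	WT	6 Cl-	498	LpH	50
13	1IYT	A2T	3 Na+	498	NpH	50
14	1Z0Q	A2T	3 Na+	498	NpH	50
15	2NAO	A2T	3 Na+	498	NpH	50
16	1IYT	D7N	2 Na+	498	NpH	50
17	1Z0Q	D7N	2 Na+	498	NpH	50
18	2NAO	D7N	2 Na+	498	NpH	50
19	1IYT	E22G	2 Na+	310	NpH	50
20	1Z0Q	E22G	2 Na+	310	NpH	50
21	2NAO	E22G	2 Na+	310	NpH	50
22	1IYT	E22G	2 Na+	498	NpH	50
23	1Z0Q	E22G	2 Na+	498	NpH	50
24	2NAO	E22G	2 Na+	498	NpH	50
25	1IYT	E22Q	2 Na+	310	NpH	50
26	1Z0Q	E22Q	2 Na+	310	NpH	50
27	2NAO	E22Q	2 Na+	310	NpH	50
28	1IYT	E22Q	2 Na+	498	NpH	50
29	1Z0Q	E22Q	2 Na+	498	NpH	50
30	2NAO	E22Q	2 Na+	498	NpH	50
31	1IYT	D23N	2 Na+	498	NpH	50
32	1Z0Q	D23N	2 Na+	498	NpH	50
33	2NAO	D23N	2 Na+	498	NpH	50
34	1IYT	G25P	3 Na+	310	NpH	50
35	1Z0Q	G25P	3 Na+	310	NpH	50
36	2NAO	G25P	3 Na+	310	NpH	50
37	1IYT	G25P	3 Na+	498	NpH	50
38	1Z0Q	G25P	3 Na+	498	NpH	50
39	2NAO	G25P	3 Na+	498	NpH	50
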