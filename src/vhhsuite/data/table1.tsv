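cluster	proteoliposomes_control	proteoliposomes_fshr_r3	cells_control	cells_fshr_r2	cells_fshr_r3	mbp_control	mbp_fshr_r2	mbp_fshr_r3	ecd_fshr_r2	ecd_fshr_r3	membranes_control	membranes_fshr_r3	total
PRC1	0	0	0	0	0	0	0	0	28890	16209	0	0	45099
1	0	200	0	0	0	0	0	952	68	34	0	0	228
6	0	0	0	0	0	0	0	560	0	0	0	0	103
11	0	114	0	49	0	0	1464	500	54	0	0	0	239
15	0	0	0	0	0	0	0	451	0	0	0	0	83
19	0	0	0	0	0	0	0	0	0	757	0	0	403
23	0	0	0	0	0	0	0	0	0	447	0	0	238
27	0	0	0	0	0	0	128	0	0	282	0	0	160
31	0	0	0	0	0	0	0	0	0	254	0	0	135
2	0	0	0	0	0	0	0	0	0	197	0	0	105
7	0	2074	0	0	0	0	0	0	249	0	0	0	269
12	0	1313	0	0	0	0	0	0	230	0	0	0	185
16	0	171	0	0	0	0	12018	0	0	19	0	0	964
35	0	114	0	0	0	0	8243	0	0	26	0	0	668
20	0	95	0	0	0	0	6715	0	0	0	0	0	533
24	0	0	0	0	0	0	4198	0	0	0	0	0	327
36	0	0	0	0	0	0	3749	0	191	0	0	0	331
28	0	0	0	59	6364	0	0	0	0	0	0	0	480
38	0	0	0	0	4256	0	0	0	0	0	0	0	313
32	0	0	0	504	2529	0	0	0	0	0	0	0	288
3	0	0	0	0	2271	0	0	0	0	0	0	0	167
8	0	0	0	178	1972	0	0	0	0	0	0	0	181
13	0	0	0	405	1822	0	0	0	0	0	0	0	216
17	0	0	0	0	1741	0	0	0	0	0	0	0	128
21	0	0	0	1846	1469	0	0	0	0	0	0	92	493
25	0	0	0	884	1278	0	0	0	0	0	0	0	273
29	0	0	0	592	163	0	0	103	0	0	0	0	151
33	0	0	0	504	340	0	0	0	0	0	0	0	127
4	0	0	0	494	476	0	0	0	0	0	0	0	135
34	0	0	0	0	0	0	0	0	0	0	0	776	93
30	0	0	0	20	0	0	0	0	0	0	0	0	4
14	0	0	0	0	0	0	0	0	0	0	0	451	54
22	0	0	0	0	0	0	0	0	0	0	0	42	5
37	0	0	0	0	0	0	2863	0	0	0	0	0	223
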