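mirna	av_chi2	targetscan_family_av	targetscan_family_members
1	44.2375		
3	55.005	23.8583	3;309;318
8	11.87		
9a	94.48	89.4917	9a;9b;9c
9b	106.515		
9c	67.48		
10	5.825		
12	22.215		
31	1.7233		
34	61.6733		
79	75.665		
92a	95.605	72.245	92a;92b;310;312;313
92b	28.3		
124	82.57		
133	48.02		
137	42.74		
184	27.405		
193	47.53		
219	2.155		
263b	5.565		
274	22.64		
276b	41.435	25.02	276a;276b
277	24.585		
278	77.63		
279	13.5	-4.104	279;286;996
287	2.255		
310	102.4833	72.245	92a;92b;310;312;313
312	32.885		
313	50.71		
315	24.59		
316	2.695		
318	26.385		
375	39.25		
932	25.87		
958	25.42		
968	35.07		
977	4.7065		
978	70.46		
980	31.04		
989	44.38		
992	7.805		
995	7.05	2.695	285;995;998
999	2.775		
1015	3.855		
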