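gene_id	av_chi2_ir	pooled	pooled_combined	microcosm	microcosm_combined	pictar	pictar_combined	mirnaorg	mirnaorg_combined	targetscan	targetscan_combined
Blimp-1	2.1158	49.9482	105.6803	15.8908	33.6217	3.4973	7.3996	14.1685	29.9777	16.3916	34.6813
Bx	5.727	58.9239	337.4571	12.5711	71.9946	10.0509	57.5614	21.5938	123.6680	14.7081	84.2331
CadN	-2.1481	148.5861	-319.1725	20.0306	-43.0271	46.4332	-99.7416	38.4779	-82.6531	43.6443	-93.7507
CG10737	18.26	71.3749	1303.3054	35.5040	648.3023	5.7567	105.1168	13.7227	250.5759	16.3916	299.3104
CG11206	-3.7402	95.6901	-357.9003	9.0084	-33.6933	8.5247	-31.8840	34.9136	-130.5839	43.2434	-161.7391
CG12918	-5.3436	52.1314	-278.5678	20.8109	-111.2046	3.3907	-18.1183	18.0949	-96.6912	9.8350	-52.5538
CG13606	1.6099	52.6384	84.7431	14.5549	23.4320	4.7616	7.6658	16.6199	26.7566	16.7020	26.8887
CG3077	1.6012	91.2297	146.0771	23.2887	37.2898	6.4559	10.3372	41.8153	66.9546	19.6699	31.4955
CG32105	2.557	43.3198	110.7687	10.3112	26.3658	2.2363	5.7182	20.9373	53.5367	9.8350	25.1480
CG33090	0.3904	82.8792	32.3560	21.1135	8.2427	4.0624	1.5859	16.7976	6.5578	40.9057	15.9696
CG3376	0.1872	42.0182	7.8637	8.3405	1.5609	5.9978	1.1225	17.8450	3.3397	9.8350	1.8406
CG3534	-4.364	48.6526	-212.3199	17.7977	-77.6690	3.4824	-15.1971	17.5376	-76.5341	9.8350	-42.9197
CG3624	3.1832	55.4638	176.5522	16.9653	54.0040	2.6852	8.5476	23.3858	74.4417	12.4274	39.5589
CG4360	4.778	47.9093	228.9108	18.0506	86.2459	2.4584	11.7464	11.0087	52.5996	16.3916	78.3190
CG4984	-2.9691	59.4745	-176.5827	18.0490	-53.5884	7.6279	-22.6477	7.6745	-22.7861	26.1230	-77.5605
CG5599	22.6593	40.5821	919.5590	8.8509	200.5549	1.0127	22.9470	12.8686	291.5939	17.8498	404.4632
CG6129	14.115	41.6798	588.3099	6.8082	96.0981	2.8427	40.1250	14.9821	211.4727	17.0467	240.6141
CG7510	6.9305	49.2790	341.5279	14.8554	102.9554	2.4046	16.6651	12.5453	86.9454	19.4736	134.9621
CG8121	-0.724	54.1836	-39.2289	7.7300	-5.5965	2.9878	-2.1632	8.4767	-6.1371	34.9891	-25.3321
CG8128	-8.1508	94.2880	-768.5205	19.9651	-162.7308	3.0917	-25.1994	54.8397	-446.9861	16.3916	-133.6042
CG8303	11.0345	49.7826	549.3262	15.8126	174.4840	3.3083	36.5052	14.2702	157.4640	16.3916	180.8730
CG8323	1.784	64.1433	114.4316	18.4807	32.9695	4.3704	7.7968	13.6601	24.3696	27.6321	49.2957
CG8360	-2.4035	56.7583	-136.4185	16.8753	-40.5598	5.7226	-13.7542	11.2122	-26.9484	22.9482	-55.1561
CG8417	-11.5805	52.5854	-608.9652	15.8653	-183.7277	4.3959	-50.9072	15.9326	-184.5075	16.3916	-189.8227
CG9376	-10.065	15.8820	-159.8522	7.2495	-72.9661	0.5563	-5.5996	3.1890	-32.0968	4.8872	-49.1895
CG9650	0.4336	62.1572	26.9522	7.6917	3.3352	7.0478	3.0560	23.3065	10.1060	24.1113	10.4549
Cpr	-15.54	47.5051	-738.2286	14.3186	-222.5113	9.1431	-142.0838	14.2084	-220.7984	9.8350	-152.8352
Dysb	1.6958	65.1018	110.3974	19.4330	32.9539	4.5585	7.7301	20.0348	33.9743	21.0755	35.7391
endoB	-16.4445	24.5428	-403.5939	0.1061	-1.7449	6.1164	-100.5814	7.4080	-121.8216	10.9122	-179.4460
Ero1L	3.1058	45.3898	140.9738	14.8674	46.1758	5.0706	15.7486	15.6169	48.5035	9.8350	30.5458
garz	45.38	31.3660	1423.3876	4.7120	213.8301	0.5962	27.0568	6.4735	293.7671	19.5843	888.7336
Gfat2	0.9978	41.9788	41.8843	15.8440	15.8083	3.1358	3.1287	13.1641	13.1345	9.8350	9.8128
Myd88	1.9035	6.4706	12.3167	4.1638	7.9258	0.0121	0.0231	2.0501	3.9023	0.2446	0.4656
Nak	0.2233	103.4518	23.1023	19.0669	4.2579	16.3947	3.6612	36.5532	8.1629	31.4370	7.0203
pdm2	1.059	25.7957	27.3176	6.5096	6.8937	0.9607	1.0173	4.8823	5.1704	13.4431	14.2362
porin	-7.7	89.8516	-691.8569	62.5375	-481.5385	2.5203	-19.4065	2.9915	-23.0343	21.8023	-167.8776
Ptp69D	1.4233	52.3718	74.5408	14.2880	20.3361	6.8889	9.8050	19.0121	27.0599	12.1828	17.3398
RASSF8	0.8924	34.0327	30.3690	4.4412	3.9631	0.7073	0.6312	8.3362	7.4388	20.5480	18.3360
raw	10.635	43.2677	460.1515	11.3523	120.7318	5.8320	62.0234	15.1805	161.4449	10.9028	115.9513
regucalcin	9.886	56.0884	554.4895	15.5743	153.9677	15.7528	155.7325	14.9263	147.5610	9.8350	97.2283
RhoGAP68F	1.5819	61.4035	97.1323	14.2428	22.5303	1.8217	2.8817	19.0121	30.0747	26.3269	41.6457
Sbf	-4.459	73.9455	-329.7229	28.9451	-129.0661	4.3431	-19.3659	17.0058	-75.8288	23.6515	-105.4621
sens	-3.6995	49.4627	-182.9872	14.7634	-54.6171	2.6482	-9.7972	8.9293	-33.0340	23.1217	-85.5388
Sirt2	-4.868	44.5340	-216.7917	15.6316	-76.0947	5.3448	-26.0184	13.7227	-66.8020	9.8350	-47.8766
SP555	9.785	61.7540	604.2626	20.8951	204.4589	7.8086	76.4074	17.9622	175.7604	15.0880	147.6358
T48	10.65	49.6111	528.3581	4.3790	46.6361	1.1091	11.8117	10.2365	109.0189	33.8865	360.8914
Thd1	0.3609	66.7116	24.0729	19.9882	7.2127	2.1996	0.7937	24.2192	8.7395	20.3047	7.3269
Tm1	5.37	37.4083	200.8823	9.7281	52.2401	3.4708	18.6380	9.6231	51.6761	14.5862	78.3281
toe	13.09	47.8611	626.5024	17.7450	232.2815	3.2504	42.5476	17.0308	222.9338	9.8350	128.7395
up	3.93	94.0563	369.6411	32.8545	129.1183	24.6085	96.7114	24.4104	95.9330	12.1828	47.8784
Vha68-1	0.625	64.4111	40.2570	9.5403	5.9627	3.4957	2.1848	26.8446	16.7779	24.5305	15.3316
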