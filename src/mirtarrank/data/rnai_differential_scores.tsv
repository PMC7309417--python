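gene_id	av_chi2_ir	microcosm	microcosm_combined	pictar	pictar_combined	mirnaorg	mirnaorg_combined	targetscan	targetscan_combined
CG15544	0.1253	1.2446	0.1559	0.0137	0.0017			0.1564	0.0196
CG1623	2.9325	14.6090	42.8407			20.3535	59.6866	13.6183	39.9357
CG17712	4.5853	16.4402	75.3831			12.5865	57.7130	9.8350	45.0962
CG3678	24.675	22.2661	549.4160			15.6470	386.0907	9.8350	242.6775
CG4893	5.8825	19.6009	115.3024			21.6375	127.2824	20.3047	119.4422
fray	-11.2926							1.0625	-11.9986
Ggamma1	1.709			10.0845	17.2344	3.4702	5.9305	18.7955	32.1215
inx2	0.1211	0.0986	0.0119			10.2664	1.2433		
Nek2	3.1163	29.1504	90.8415			13.6972	42.6847	9.8350	30.6487
nord	0.0034			0.0120	0.0000	3.5694	0.0122	0.3669	0.0013
Paf-AHalpha	-3.1485	2.4176	-7.6118						
Pif1B	18.035	8.5626	154.4266			5.5158	99.4768	18.7342	337.8716
sna	2.1454	0.5810	1.2464			0.3121	0.6696	6.6337	14.2319
tor	1.5355	16.4688	25.2879			11.3850	17.4817	16.3916	25.1693
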