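gene_id	line_id	median_survival	chi2	p_value	direction
Blimp-1	108374/KK	27.0	3.909	0.048	shorten
Blimp-1	34978/GD	33.0	0.3226	0.57	none
Bx	106495/KK	24.0	4.166	0.0412	shorten
Bx	2971/GD	27.0	7.288	0.0069	shorten
CadN	101644/KK	31.0	0.0939	0.7593	none
CadN	1092/GD	31.0	4.39	0.0361	extend
CG10737	106383/KK	32.0	0.18	0.6714	none
CG10737	8996/GD	19.0	36.34	1e-05	shorten
CG11206	42943/GD	35.0	8.48	1e-05	extend
CG11206	42945/GD	28.0	0.9996	0.3174	none
CG12918	105503/KK	35.0	10.69	0.0011	extend
CG12918	38082/GD	31.0	0.0029	0.9573	none
CG13606	109997/KK	31.0	3.162	0.0754	none
CG13606	45481/GD	29.0	0.0578	0.81	none
CG3077	109618/KK	31.0	3.162	0.0754	none
CG3077	25630/GD	29.0	0.0404	0.8301	none
CG32105	108747/KK	28.0	2.508	0.1132	none
CG32105	51267/GD	28.5	2.606	0.1064	none
CG33090	23407/GD	29.0	0.5904	0.4423	none
CG33090	28033/GD	28.0	0.1904	0.6626	none
CG3376	12226/GD	29.0	0.3743	0.5406	none
CG3534	109666/KK	35.0	8.728	0.0031	extend
CG3534	41276/GD	30.0	4.522e-07	0.9995	none
CG3624	36304/GD	27.0	0.4244	0.5148	none
CG3624	956/GD	26.0	5.942	0.0148	shorten
CG4360	105000/KK	25.0	2.637	0.1044	none
CG4360	26520/GD	25.0	6.919	0.0085	shorten
CG4984	10057/GD	31.0	0.4919	0.4831	none
CG4984	107854/KK	33.0	6.43	0.0112	extend
CG5599	106456/KK	29.0	0.9585	0.3276	none
CG5599	16505/GD	18.0	44.36	1e-05	shorten
CG6129	110171/KK	23.0	12.24	0.0005	shorten
CG6129	22094/GD	21.0	15.99	1e-05	shorten
CG7510	105469/KK	31.0	1.421	0.2333	none
CG7510	8532/GD	24.0	12.44	0.0004	shorten
CG8121	105866/KK	33.0	5.677	0.0172	extend
CG8121	43952/GD	30.0	2.238	0.1347	none
CG8121	43953/GD	31.0	1.267	0.2603	none
CG8128	107574/KK	31.0	0.0685	0.7936	none
CG8128	97740/GD	34.5	16.37	1e-05	extend
CG8303	107101/KK	28.0	7.389	0.0066	shorten
CG8303	4918/GD	25.0	14.68	0.0001	shorten
CG8323	4861/GD	29.0	3.568	0.0589	none
CG8360	23461/GD	34.0	4.807	0.0283	extend
CG8417	106461/KK	38.0	23.17	1e-05	extend
CG8417	49509/GD	31.0	0.009	0.9244	none
CG9376	106062/KK	34.0	20.13	1e-05	extend
CG9650	104402/KK	33.0	0.8672	0.3517	none
CG9650	23170/GD	29.5	2.53e-05	0.996	none
Cpr	107422/KK	38.0	31.08	1e-05	extend
Dysb	106957/KK	32.0	1.639	0.2005	none
Dysb	34354/GD	29.0	0.1023	0.7491	none
Dysb	34355/GD	34.0	3.346	0.0674	none
endoB	104712/KK	38.0	39.14	1e-05	extend
endoB	29291/GD	24.0	6.251	0.0124	shorten
Ero1L	11045/KK	31.0	0.0187	0.8912	none
Ero1L	51169/GD	25.0	6.193	0.0128	shorten
garz	42140/GD	17.0	42.48	1e-05	shorten
garz	42141/GD	16.0	48.28	1e-05	shorten
Gfat2	105129/KK	31.0	0.9625	0.3265	none
Gfat2	17187/GD	27.0	1.033	0.3094	none
Myd88	106198/KK	31.0	1.749	0.186	none
Myd88	25402/GD	28.0	2.058	0.1515	none
Nak	109507/KK	29.0	0.4342	0.5099	none
Nak	35482/GD	29.0	0.0124	0.9112	none
pdm2	102126/KK	31.0	2.118	0.1455	none
porin	101336/KK	38.0	15.4	1e-05	extend
Ptp69D	27091/GD	27.0	2.477	0.1155	none
Ptp69D	40631/GD	29.0	0.3696	0.5432	none
RASSF8	105823/KK	31.0	0.9831	0.3214	none
RASSF8	26520/GD	27.0	0.8016	0.3706	none
raw	101255/KK	35.0	17.59	1e-05	extend
raw	24532/GD	14.0	38.86	1e-05	shorten
regucalcin	105509/KK	31.0	1.022	0.312	none
regucalcin	39945/GD	22.0	18.75	1e-05	shorten
RhoGAP68F	107775/KK	28.0	3.087	0.0789	none
RhoGAP68F	34520/GD	31.0	0.0767	0.7818	none
Sbf	22317/GD	35.0	8.918	0.0028	extend
sens	106028/KK	34.0	7.399	0.0065	extend
Sirt2	103790/KK	30.0	5.736	0.0166	extend
Sirt2	21999/GD	31.0	4.0	0.0455	extend
SP555	39821/GD	19.0	19.57	1e-05	shorten
T48	100334/KK	11.0	21.3	1e-05	shorten
Thd1	110439/KK	29.0	0.7217	0.3956	none
Tm1	34119/GD	19.0	10.74	0.001	shorten
toe	107893/KK	23.0	15.44	1e-05	shorten
toe	46515/GD	27.0	10.74	0.001	shorten
up	27853/GD	25.0	7.86	0.0051	shorten
Vha68-1	17102/GD	28.0	0.7032	0.4017	none
Vha68-1	46397/GD	28.0	0.5468	0.4596	none
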