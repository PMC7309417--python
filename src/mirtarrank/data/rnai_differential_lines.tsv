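gene_id	line_id	median_survival	chi2	p_value	direction
CG15544	39997/GD	28.0	0.2505	0.6167	none
CG1623	107655/KK	26.0	3.05	0.0808	none
CG1623	32665/GD	27.0	2.815	0.0934	none
CG17712	105119/KK	31.0	0.3146	0.5749	none
CG17712	32987/GD	26.0	8.856	0.0029	shorten
CG3678	26267/GD	22.0	35.99	1e-05	shorten
CG3678	49793/GD	24.0	13.36	0.0003	shorten
CG4893	110188/KK	31.0	1.085	0.2977	none
CG4893	22356/GD	26.0	10.68	0.0011	shorten
fray	101058/KK	38.0	22.86	1e-05	extend
fray	27944/GD	31.0	0.2749	0.6001	none
Ggamma1	28894/GD	32.5	3.418	0.0645	none
inx2	102194/KK	33.0	0.2422	0.6226	none
Nek2	103408/KK	33.0	0.6786	0.4101	none
Nek2	40052/GD	26.0	5.554	0.0184	shorten
nord	39901/GD	31.0	0.0068	0.9341	none
Paf-AHalpha	101683/KK	33.0	6.297	0.0121	extend
Pif1B	49782/GD	17.0	36.07	1e-05	shorten
sna	50003/GD	32.0	3.082	0.0791	none
sna	50004/GD	33.0	0.1852	0.667	none
sna	6232/GD	31.5	3.169	0.0751	none
tor	101154/KK	31.0	2.557	0.1098	none
tor	36280/GD	31.0	0.514	0.4734	none
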