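category	pas_id	symbol	disorders	pass_per_gene	major_pas	stat_a	stat_b	stat_c	comparison
cycle24	550479	Abi2	AD(1), DEP(1)	5		2.61E-03	1.14E-01	22
cycle24	126847	Agfg2	AD(1)	2		1.04E-02	2.64E-01	21
cycle24	61185	Arl3	ANX(1), BIP(2), SZC(6)	3		3.51E-02	5.26E-01	16
cycle24	234171	Brd8	SCZ(2)	3		5.51E-03	1.81E-01	10
cycle24	188939	Ccdc25	BIP(1)	6	mPAS	3.66E-02	5.37E-01	4
cycle24	82922	Cdip1	SCZ(2)	3		9.97E-05	1.51E-02	17
cycle24	392202	Chmp3	ANX(1)	4		9.61E-03	2.47E-01	7
cycle24	392209	Chmp3	ANX(1)	4		3.11E-02	4.94E-01	18
cycle24	210841	Ddhd2	SCZ(18)	2	mPAS	2.57E-03	1.11E-01	18
cycle24	330991	Elp4	ANX(2), DEP(1)	2	mPAS	1.27E-03	7.33E-02	22
cycle24	331015	Elp4	ANX(2), DEP(1)	2		2.49E-02	4.38E-01	1
cycle24	494157	Emc2	ANX(11)	4	mPAS	5.60E-04	4.36E-02	16
cycle24	141301	Enah	ANX(7), BIP(1)	4		1.51E-02	3.25E-01	21
cycle24	332926	Frmd5	ANX(1), DEP(1)	6		1.15E-02	2.78E-01	2
cycle24	205543	Gatad2a	SCZ(1)	3		9.60E-03	2.48E-01	19
cycle24	204624	Grid1	ANX(1)	2		2.47E-04	2.66E-02	6
cycle24	121855	Hip1r	SCZ(1), AD(1)	2		3.83E-02	5.54E-01	17
cycle24	61332	Ina	SCZ(1)	3	mPAS	5.32E-03	1.76E-01	23
cycle24	351590	Map1a	SCZ(1)	11		1.31E-05	4.05E-03	2
cycle24	95493	Mapt	AD(1), ANX(2), ASD(1). DEP(2), MDD(2), PD(2), PTSD(2), SCZ(2)	9		1.13E-02	2.71E-01	1
cycle24	213927	Ntrk2	ANX(1)	10	mPAS	2.02E-02	3.86E-01	20
cycle24	213950	Ntrk2	ANX(1)	10		3.24E-02	5.05E-01	2
cycle24	55226	Pnpla2	ADHD(1)	2		2.78E-03	1.18E-01	20
cycle24	514594	Rbm6	DEP(1)	4	mPAS	2.06E-02	3.90E-01	18
cycle24	549537	Sf3b1	SCZ(1)	4		8.47E-04	5.47E-02	8
cycle24	286602	Ssbp2	PTSD(1)	5		1.03E-03	6.43E-02	17
cycle24	131036	Svop	Anx(2)	4		8.34E-03	2.28E-01	15
cycle24	17074	Wdr73	SCZ(2)	2		2.27E-02	4.09E-01	3
cycle12	550473	Abi2	AD(1), DEP(1)	5	mPAS	3.50E-02	6.33E-01	6
cycle12	61185	Arl3	ANX(1), BIP(2), SZC(6)	3		1.84E-02	4.39E-01	5
cycle12	98600	Cadm2	BIP(1)	16		3.40E-06	2.14E-03	5
cycle12	392206	Chmp3	ANX(1)	4	mPAS	2.61E-02	5.18E-01	4
cycle12	287927	Ercc8	SCZ(1)	2		8.29E-03	2.72E-01	6
cycle12	200908	Fgfr1	SCZ(1)	5		2.82E-02	5.55E-01	8
cycle12	538044	Hecw2	SCZ(1)	6		1.46E-04	2.16E-02	7
cycle12	61328	Ina	SCZ(1)	3		1.75E-05	5.35E-03	11
cycle12	77702	Lsm12	BIP(1)	2	mPAS	8.17E-03	2.58E-01	5
cycle12	529393	Mon1a	DEP(1), MDD(1), PTSD(1)	2	mPAS	9.21E-04	7.38E-02	4
cycle12	525326	Myo1e	SCZ(1)	2	mPAS	1.16E-02	3.17E-01	5
cycle12	90245	Pitpna	AD(1)	8		2.01E-02	4.61E-01	2
cycle12	258834	Pskh1	SCZ(1)	2		3.98E-03	1.76E-01	7
cycle12	145571	Rab29	PD(1)	3	mPAS	3.33E-04	4.04E-02	6
cycle12	89414	Rabep1	SCZ(13)	4		5.16E-06	2.72E-03	4
cycle12	22342	Setd1a	PD(1)	2		2.67E-02	5.45E-01	3
cycle12	390670	Snca	AD(1),PD(7),SCZ(3)	4		3.35E-03	1.57E-01	10
cycle12	18304	Usp35	ANX(2)	2	mPAS	8.36E-04	6.91E-02	10
cycle12	218787	Wac	BIP(1)	4		1.83E-05	5.61E-03	10
de	467701	Mark3	SCZ(1)	5		3.18	5.81E-09	6.94E-06	ZT10_vs_R4
de	467700	Mark3	SCZ(1)	5		3.00	7.13E-08	4.95E-05	ZT10_vs_R4
de	191750	Ndfip2	SCZ(1).BIP(1)	5		-1.15	2.55E-08	2.19E-05	ZT10_vs_R4
de	218787	Wac	BIP(1)	4		-1.51	1.63E-04	1.30E-02	ZT10_vs_R4
de	549537	Sf3b1	SCZ(1)	4		-1.30	6.47E-04	3.15E-02	ZT10_vs_R4
de	35839	Mtrf1l	SCZ(1)	4		-1.60	9.64E-04	4.08E-02	ZT10_vs_R4
de	205547	Gatad2a		3	mPAS	1.03	9.24E-05	9.16E-03	ZT10_vs_R4
de	205543	Gatad2a	SCZ(1)	3		1.42	2.29E-03	7.24E-02	ZT10_vs_R4
de	261774	Spg7	SCZ(2)	3	mPAS	2.17	2.75E-04	1.89E-02	ZT10_vs_R4
de	519450	Snx19	ADHD(1), BIP(1), SCZ(3)	3		-1.18	3.65E-04	2.20E-02	ZT10_vs_R4
de	78129	Plekhm1	ANX(1), DEP(1), PD(1), PTSD(1), SCZ(1)	3	mPAS	1.96	2.59E-03	7.74E-02	ZT10_vs_R4
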