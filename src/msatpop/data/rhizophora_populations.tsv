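species	country	locality	code	n	a_obs	a_rarefied	a_effective	ho	ho_se	he	he_se	fis	fis_se	t
R. apiculata	China	Qinglan Harbor, Hainan	CHN.QLH	25	2.54	2.16	1.38	0.191	0.047	0.225	0.055	0.173	0.070	0.705
R. apiculata	China	Tielu Harbor, Hainan	CHN.TLH	25	2.23	1.95	1.41	0.249	0.057	0.251	0.050	0.028	0.083	0.946
R. apiculata	Philippines	Panay Island	PHP.PNL	17	4.46	3.89	2.79	0.457	0.090	0.504	0.081	0.123	0.089	0.781
R. apiculata	Micronesia	Chuuk	MCN.CHK	15	2.46	2.25	1.42	0.226	0.050	0.247	0.053	0.120	0.115	0.786
R. apiculata	Micronesia	Kosrae	MCN.KSR	19	2.23	1.94	1.32	0.190	0.059	0.191	0.056	0.033	0.099	0.936
R. apiculata	Micronesia	Yap	MCN.YAP	19	3.69	3.17	2.21	0.368	0.067	0.466	0.065	0.235	0.092	0.619
R. apiculata	U.S.A	Guam	USA.GM	10	2.31	2.31	1.41	0.231	0.065	0.231	0.055	0.053	0.093	0.899
R. apiculata	Malaysia	Blue Lagoon, Cape Rachado	MLS.BLG	20	3.38	2.96	2.02	0.515	0.094	0.414	0.068	-0.221	0.076	1.567
R. apiculata	Malaysia	Kampung Sementa, Klang	MLS.KPS	18	3.46	2.92	1.83	0.303	0.063	0.349	0.070	0.159	0.074	0.726
R. apiculata	Sri Lanka	Pambala, Puttalam	SRL.PBL	22	2.85	2.39	1.54	0.196	0.051	0.292	0.058	0.350	0.117	0.481
R. apiculata	Thailand	Khao Khanap Nam, Krabi	THL.KKN	17	3.38	2.88	1.82	0.308	0.075	0.335	0.075	0.111	0.078	0.800
R. apiculata	Thailand	Ranong	THL.RNG	24	4.15	3.28	1.92	0.372	0.065	0.400	0.064	0.091	0.074	0.833
R. apiculata	Thailand	Phang Nga Bay, Phunket	THL.PNB	27	4.15	3.16	2.02	0.353	0.062	0.405	0.070	0.146	0.079	0.745
R. apiculata	Thailand	Mu Ko Thale Tai National Park	THL.MNP	16	4.54	4.09	2.82	0.342	0.054	0.533	0.073	0.388	0.089	0.441
R. apiculata	Indonesia	North Sulawesi	IDN.NSL	11	3.77	3.70	2.45	0.448	0.081	0.451	0.083	0.055	0.044	0.896
R. apiculata	Indonesia	Tarakan	IDN.TRK	6	3.31	NA	2.12	0.423	0.079	0.447	0.068	0.143	0.117	0.750
R. apiculata	Australia	Cato River, Northern Territory	AUS.CTR	21	3.15	2.56	1.58	0.282	0.060	0.286	0.059	0.038	0.062	0.927
R. apiculata	Australia	Embley River, Queensland	AUS.EMB	11	2.54	2.50	1.90	0.378	0.091	0.379	0.076	0.050	0.108	0.905
R. apiculata	Australia	Daintree River, Queensland	AUS.DTR	26	2.46	1.92	1.21	0.124	0.041	0.139	0.043	0.125	0.114	0.778
R. apiculata	Australia	Trinity Inlet, Queensland	AUS.TRI	13	1.85	1.78	1.19	0.136	0.038	0.138	0.037	0.055	0.071	0.896
R. mucronata	Kenya	Mida Creek	KNY.MDC	13	2.69	2.59	1.90	0.290	0.094	0.316	0.073	0.121	0.146	0.784
R. mucronata	Thailand	Phang Nga Bay, Phuket	THL.PNB	23	2.77	2.24	1.33	0.221	0.072	0.217	0.040	0.005	0.114	0.990
R. mucronata	Micronesia	Yap	MCN.YAP	15	3.85	3.43	1.95	0.415	0.054	0.469	0.029	0.148	0.102	0.742
R. mucronata	Micronesia	Kosrae	MCN.KSR	8	2.92	NA	1.80	0.308	0.087	0.342	0.072	0.166	0.132	0.715
R. mucronata	Indonesia	Tarakan	IDN.TRK	6	3.08	NA	2.11	0.359	0.073	0.466	0.058	0.314	0.114	0.522
R. mucronata	Indonesia	North Sulawesi	IDN.NSL	13	4.08	3.75	1.99	0.432	0.072	0.445	0.053	0.069	0.087	0.871
R. mucronata	Malaysia	Kampung Sementa, Klang	MLS.KPS	18	3.00	2.60	1.62	0.278	0.086	0.296	0.063	0.090	0.125	0.835
R. mucronata	Philippines	Panay Island	PHP.PNL	22	4.31	3.35	1.93	0.280	0.070	0.370	0.071	0.266	0.112	0.580
R. mucronata	Sri Lanka	Rekawa	SRL.RKW	8	1.92	NA	1.36	0.250	0.085	0.212	0.055	-0.113	0.176	1.255
R. mucronata	Sri Lanka	Pambala, Puttalam	SRL.PBL	12	2.46	2.34	1.56	0.321	0.078	0.310	0.053	0.009	0.113	0.982
R. mucronata	Australia	Daintree River, Queensland	AUS.DTR	24	3.00	2.37	1.36	0.189	0.072	0.224	0.045	0.175	0.141	0.702
R. mucronata	Australia	Trinity Inlet, Queensland	AUS.TRI	7	3.69	NA	2.56	0.330	0.071	0.583	0.034	0.495	0.112	0.338
R. stylosa	Japan	Iriomote Island	JPN.IRT	24	2.85	2.27	1.43	0.252	0.083	0.239	0.055	-0.035	0.132	1.073
R. stylosa	China	Danzhou, Hainan	CHN.DNZ	12	1.77	1.73	1.36	0.179	0.076	0.187	0.061	0.083	0.189	0.847
R. stylosa	China	Dongzhai Harbor, Hainan	CHN.DZH	21	2.00	1.82	1.36	0.216	0.094	0.177	0.061	-0.195	0.135	1.484
R. stylosa	Philippines	Panay Island	PHP.PNL	18	3.23	2.91	1.96	0.248	0.089	0.356	0.078	0.330	0.137	0.504
R. stylosa	Micronesia	Chuuk	MCN.CHK	20	4.00	3.23	2.11	0.338	0.095	0.392	0.079	0.162	0.128	0.721
R. stylosa	Micronesia	Kosrae	MCN.KSR	12	3.15	2.97	1.85	0.397	0.089	0.382	0.065	0.004	0.126	0.992
R. stylosa	Micronesia	Yap	MCN.YAP	20	2.62	2.29	1.54	0.288	0.077	0.295	0.056	0.047	0.111	0.910
R. stylosa	U.S.A	Guam	USA.GM	17	1.77	1.68	1.28	0.199	0.091	0.149	0.058	-0.309	0.140	1.894
R. stylosa	Malaysia	Teluk Pelanduk	MLS.TKP	17	3.08	2.43	1.38	0.267	0.089	0.205	0.054	-0.277	0.060	1.766
R. stylosa	Indonesia	North Sulawesi	IDN.NSL	17	3.77	3.24	2.01	0.448	0.094	0.404	0.070	-0.078	0.095	1.169
R. stylosa	Kiribati	Butaritari Island	KRB.BTR	17	1.69	1.60	1.37	0.190	0.093	0.186	0.067	0.011	0.275	0.978
R. stylosa	Kiribati	Tarawa island	KRB.TRW	19	2.23	1.99	1.42	0.194	0.084	0.217	0.064	0.131	0.178	0.768
R. stylosa	Fiji	Suva Point	FJ.SVP	13	2.15	2.02	1.33	0.148	0.073	0.168	0.058	0.157	0.178	0.729
R. stylosa	Australia	Cato River, Northern Territory	AUS.CTR	23	6.15	5.08	3.66	0.645	0.057	0.650	0.051	0.029	0.050	0.944
R. stylosa	Australia	Embley River, Queensland	AUS.EMB	16	5.23	4.65	3.04	0.630	0.071	0.600	0.056	-0.018	0.057	1.037
R. stylosa	Australia	Daintree River, Queensland	AUS.DTR	24	3.62	2.92	1.90	0.462	0.073	0.423	0.056	-0.070	0.084	1.151
R. stylosa	Australia	Trinity Inlet, Queensland	AUS.TRI	14	3.00	2.75	1.73	0.418	0.075	0.370	0.053	-0.094	0.085	1.208
R. stylosa	Australia	Moreton Bay, Queensland	AUS.MTB	16	3.46	2.98	1.65	0.370	0.073	0.348	0.052	-0.033	0.102	1.068
R. stylosa	Australia	Shoalwater Bay, Queensland	AUS.SLB	6	2.46	NA	1.87	0.487	0.081	0.415	0.052	-0.086	0.118	1.188
R. stylosa	Australia	Tallebudgera Creek, Queensland	AUS.TBC	32	2.92	2.33	1.57	0.250	0.071	0.320	0.049	0.233	0.146	0.622
R. stylosa	Australia	Corindi River, New South Wales	AUS.CDR	21	3.08	2.53	1.57	0.282	0.081	0.323	0.048	0.150	0.160	0.739
R. stylosa	Australia	Tweed River, New South Wales	AUS.TDR	25	2.92	2.27	1.45	0.286	0.087	0.247	0.059	-0.139	0.127	1.323
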