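gene1	gene2	class	replicon1	replicon2	length	divergence	ka	ks	omega	correlation	cosine	function
RSP_1647	RSP_3650	in	CI	CII	312	13	0.0207	0.7894	0.0262	0.7507	0.9805	Protease
RSP_6194	RSP_6200	in	CII	CII	140	4	0.0174	0.4721	0.0369			Hypothetical
RSP_3624	RSP_3792	in	CII	CII	238	8	0.0318	0.8434	0.0377	0.7706	0.9452	Hypothetical
RSP_2482	RSP_4189	in	PC	PD	294	6	0.0270	0.5608	0.0481	0.9162	0.9250	Receptor
RSP_2064	RSP_6012	in	CI	CI	126	11	0.0485	0.9247	0.0525			Hypothetical
RSP_4252	RSP_3907	in	PD	PA	163	2	0.0050	0.0757	0.0658			Hypothetical
RSP_1653	RSP_6190	in	CI	CII	208	18	0.0821	1.0949	0.0750			Hypothetical
RSP_3908	RSP_4251	in	PA	PD	185	1	0.0023	0.0279	0.0811			Hypothetical
RSP_1638	RSP_2062	in	CI	CI	126	5	0.0406	0.4615	0.0881	0.7369	0.7604	Hypothetical
RSP_1645	RSP_3652	in	CI	CII	419	4	0.0565	0.5853	0.0965	0.9933	0.9694	Phage-related
RSP_2063	RSP_1639	in	CI	CI	147	9	0.0317	0.3017	0.1051	0.9995	0.9700	Hypothetical
RSP_3627	RSP_3784	in	CII	CII	448	5	0.0180	0.1697	0.1061			Protease
RSP_7390	RSP_3896	in	PD	PA	413	15	0.0759	0.6951	0.1091			Transposase
RSP_1956	RSP_6196	in	CI	CII	124	8	0.0396	0.2751	0.1439			Hypothetical
RSP_4138	RSP_3902	in	PD	PA	265	4	0.0156	0.1028	0.1513			Hypothetical
RSP_1951	RSP_3622	in	CI	CII	116	4	0.0242	0.1428	0.1692	0.2186	0.7307	Hypothetical
RSP_4178	RSP_3012	in	PD	CII	119	26	0.1629	0.7886	0.2066	0.5797	0.9629	Transposase
RSP_2061	RSP_1637	in	CI	CI	70	15	0.0548	0.2219	0.2467	0.1230	0.1230	Hypothetical
RSP_6035	RSP_3772	in	CI	CII	113	36	0.2654	0.9499	0.2794			Hypothetical
RSP_3904	RSP_7352	in	PA	PE	638	2	0.3479	1.0456	0.3327			Conjugation
RSP_3628	RSP_3786	in	CII	CII	106	16	0.1400	0.3513	0.3985	0.1197	0.8483	Hypothetical
RSP_1966	RSP_3007	in	CI	CII	242	1	0.0279	0.0577	0.4842	0.9688	0.9963	Transposase
RSP_3894	RSP_3978	in	PA	PB	276	4	0.0620	0.1005	0.6171	0.0315	0.9396	Transport
RSP_1955	RSP_3647	in	CI	CII	219	28	0.2077	0.2090	0.9937	0.7644	0.8779	Hypothetical
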