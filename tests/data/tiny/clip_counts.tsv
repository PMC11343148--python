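transcript_id	Control_CLIP_1	Control_CLIP_2	Control_CLIP_3	Control_CLIP_4	Opto_CLIP_1	Opto_CLIP_2	Opto_CLIP_3	Opto_CLIP_4
G00000.1	227	131	116	275	42	4	12	14
G00001.1	144	67	36	61	44	4	19	28
G00002.1	111	146	105	181	50	20	34	29
G00003.1	110	122	135	152	25	34	24	42
G00004.1	647	433	468	367	194	72	80	107
G00005.1	289	133	145	98	479	394	368	501
G00006.1	1169	1129	898	1567	109	98	73	96
G00007.1	381	375	462	433	190	120	58	110
G00008.1	46	39	110	75	21	24	8	23
G00009.1	373	345	234	189	988	620	437	516
G00010.1	75	239	127	217	51	11	18	11
G00011.1	27	26	45	98	24	16	13	11
G00012.1	14034	11560	16912	10632	40148	49503	47232	42455
G00013.1	71	91	93	53	11	11	15	29
G00014.1	8	3	10	5	2	0	1	0
G00015.1	1020	666	564	531	225	131	98	155
G00016.1	1151	2155	557	1329	418	222	373	882
G00017.1	963	529	768	1395	295	199	178	308
G00018.1	653	267	541	1034	457	202	166	327
G00019.1	32	27	58	31	4	6	1	6
G00020.1	42	52	50	93	46	22	21	10
G00021.1	1689	874	988	1643	258	224	462	304
G00022.1	1083	1097	806	1055	570	185	379	635
G00023.1	151	250	138	192	42	21	26	21
G00024.1	374	682	785	449	148	152	156	276
G00025.1	2441	2076	1340	1389	411	294	223	345
G00026.1	55	86	29	55	13	17	13	18
G00027.1	2662	1824	1753	2351	566	326	355	266
G00028.1	2930	3066	1081	2295	33	25	20	55
G00029.1	4011	8607	9924	6939	3708	627	1194	2059
G00030.1	39	33	12	27	8	3	4	10
G00031.1	1411	816	554	913	318	332	145	359
G00032.1	2117	1519	1948	1431	693	272	632	698
G00033.1	25	22	16	17	7	5	3	3
G00034.1	322	460	329	738	197	80	67	110
G00035.1	44	43	52	28	13	14	11	7
G00036.1	2	6	9	7	3	2	5	5
G00037.1	254	374	233	142	93	27	59	38
G00038.1	657	538	594	714	107	127	81	58
G00039.1	230	176	175	141	10	2	0	4
G00040.1	68	85	48	114	32	13	19	13
G00041.1	13	32	26	78	10	3	9	17
G00042.1	149	195	169	219	546	382	359	1260
G00043.1	2236	2170	3147	2953	1025	373	432	420
G00044.1	2162	1816	908	1604	485	244	319	797
G00045.1	192	395	180	176	58	33	64	73
G00046.1	68	56	18	58	57	20	24	23
G00047.1	1016	665	449	912	2084	1091	3079	1070
G00048.1	944	771	847	746	225	252	293	177
G00049.1	1203	2016	1679	1000	118	207	145	372
Neurod6.1	2224	2887	2976	5193	1726	546	629	2042
Camk2a.1	496	276	273	321	183	41	123	110
Rbfox3.1	2280	1849	1866	1648	874	1009	581	552
Snap25.1	468	422	334	635	174	160	105	162
Nrgn.1	413	443	364	273	131	103	61	237
Hpca.1	528	838	428	1201	213	131	138	320
Crym.1	71	121	81	54	35	12	15	27
Chn1.1	64	126	137	159	22	50	28	19
Gad2.1	49	86	53	41	6	11	16	18
Sst.1	173	195	116	121	12	21	42	26
Calb2.1	2123	2101	1709	2021	601	587	196	920
Pdgfra.1	5	6	1	6	2	7	1	4
Ptprz1.1	88	67	106	58	16	13	22	19
Mag.1	49	20	25	33	13	8	9	12
Mal.1	12	17	12	11	3	8	9	8
Mbp.1	50	68	40	149	23	7	15	17
Mobp.1	32	50	29	83	17	19	5	22
Plp1.1	75	142	92	88	28	20	16	33
Gfap.1	8	18	18	15	1	3	2	1
Glul.1	0	0	0	0	0	0	0	1
Aqp4.1	175	363	307	217	105	60	76	105
Aldh1l1.1	129	327	132	208	58	48	30	82
Pla2g7.1	45	42	38	37	23	3	9	20
Slc1a3.1	215	152	109	146	50	47	53	49
Aldoc.1	107	99	83	80	23	20	12	41
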