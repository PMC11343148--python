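transcript_id	Control_RiboIP_1	Control_RiboInput_1	Control_RiboIP_2	Control_RiboInput_2	Control_RiboIP_3	Control_RiboInput_3	Opto_RiboIP_1	Opto_RiboInput_1	Opto_RiboIP_2	Opto_RiboInput_2	Opto_RiboIP_3	Opto_RiboInput_3
G00000.1	43	33	33	30	31	47	74	43	71	43	66	27
G00001.1	72	85	83	84	92	72	113	82	101	126	78	74
G00002.1	180	221	154	124	152	156	142	148	124	122	193	174
G00003.1	31	13	9	26	20	16	17	20	25	25	14	10
G00004.1	439	656	728	622	431	424	725	369	381	546	567	338
G00005.1	206	196	231	258	297	259	300	362	256	331	238	305
G00006.1	205	183	266	210	210	183	602	227	463	228	370	208
G00007.1	445	297	551	460	601	422	218	333	425	322	463	354
G00008.1	50	63	63	80	57	87	66	38	54	70	65	54
G00009.1	598	403	741	512	344	491	409	541	446	625	378	552
G00010.1	97	124	104	159	127	123	91	84	110	110	111	115
G00011.1	81	61	78	72	29	65	48	45	69	63	57	71
G00012.1	18816	22277	16022	20857	15444	17046	24752	18222	26551	13240	18442	11643
G00013.1	131	65	66	113	92	54	72	56	82	116	63	43
G00014.1	9	6	8	7	7	12	6	5	6	4	7	5
G00015.1	769	795	776	545	693	643	554	730	553	554	544	647
G00016.1	1432	1982	1977	2292	1398	3360	2721	2102	2165	2072	2978	2232
G00017.1	792	829	1141	812	1282	790	688	779	1437	1387	1031	666
G00018.1	767	719	836	733	659	909	1153	740	1378	725	1032	1066
G00019.1	40	32	34	28	41	29	27	43	31	29	14	24
G00020.1	7	9	21	14	6	12	8	8	13	11	16	7
G00021.1	214	172	208	126	221	164	168	111	212	163	203	173
G00022.1	854	1448	926	1027	1021	1155	1058	1135	1094	1063	1437	1419
G00023.1	153	88	218	131	155	88	188	132	166	89	114	161
G00024.1	579	541	732	646	1184	692	728	614	883	561	666	549
G00025.1	331	146	237	212	256	211	247	190	237	147	211	202
G00026.1	72	57	59	35	67	52	59	53	33	60	66	60
G00027.1	1710	1946	1960	2274	2515	2103	2473	1872	2036	1534	1734	2461
G00028.1	284	229	328	269	420	288	160	384	153	366	155	361
G00029.1	1044	937	1101	875	1167	699	865	1017	690	941	967	1575
G00030.1	35	22	30	30	32	16	28	21	25	28	38	29
G00031.1	858	517	880	715	993	1156	995	1040	1001	1124	932	840
G00032.1	1651	2241	2331	1762	1414	2237	1761	2404	1585	2296	3406	1886
G00033.1	19	29	20	15	17	17	24	16	27	30	8	19
G00034.1	685	270	440	412	290	497	247	468	476	343	555	533
G00035.1	65	44	54	38	66	54	53	78	46	47	32	49
G00036.1	8	13	9	16	11	12	13	14	16	17	13	5
G00037.1	318	74	248	198	258	198	177	175	188	204	211	217
G00038.1	946	393	596	483	753	642	557	486	678	558	498	488
G00039.1	38	27	31	29	23	21	18	30	12	16	13	33
G00040.1	102	79	74	103	99	64	79	124	107	74	90	102
G00041.1	45	34	21	42	41	26	32	25	53	36	30	23
G00042.1	213	286	233	289	203	304	333	217	389	207	177	378
G00043.1	2687	1589	2668	2048	2393	2307	2830	2790	2046	1668	2253	1635
G00044.1	1519	1488	1424	1663	2402	1568	1758	1313	1160	982	2079	1252
G00045.1	279	191	233	132	223	137	200	225	301	249	160	168
G00046.1	65	80	64	69	59	53	126	47	110	71	104	88
G00047.1	1090	529	802	535	481	795	923	1034	1223	689	1146	913
G00048.1	976	1645	823	1222	1126	1221	1166	1054	1360	690	930	1331
G00049.1	1474	1199	865	1886	1833	1219	1048	943	579	1107	802	1226
Neurod6.1	3116	1076	3936	1228	5009	1007	3713	746	2948	898	4622	862
Camk2a.1	301	96	350	64	554	143	444	82	391	67	414	70
Rbfox3.1	1978	928	2134	477	2315	793	2502	800	3995	679	3106	681
Snap25.1	505	196	454	112	452	179	681	206	725	127	594	162
Nrgn.1	457	90	501	74	390	82	682	82	461	122	589	83
Hpca.1	777	193	932	158	603	121	680	142	634	179	780	238
Crym.1	97	21	106	27	68	23	122	30	90	29	105	8
Chn1.1	109	42	125	55	82	34	190	29	132	37	157	43
Gad2.1	64	165	73	297	82	272	61	237	67	205	40	151
Sst.1	200	576	141	399	135	500	92	491	140	410	119	626
Calb2.1	1872	8972	2018	8606	1672	8983	1949	13572	2388	7091	2914	12921
Pdgfra.1	8	30	7	29	2	29	5	24	10	23	6	25
Ptprz1.1	52	267	106	245	67	132	72	247	70	279	52	201
Mag.1	28	102	32	133	50	120	27	139	39	126	39	86
Mal.1	29	55	19	49	9	83	11	41	12	60	26	76
Mbp.1	115	375	86	283	70	310	49	324	52	300	86	338
Mobp.1	70	192	46	285	77	282	62	334	77	344	61	308
Plp1.1	91	217	83	206	90	148	75	224	72	255	85	311
Gfap.1	19	63	13	57	9	49	18	38	16	49	8	50
Glul.1	0	2	0	10	0	3	1	6	2	3	2	0
Aqp4.1	272	1178	217	674	279	815	374	1312	316	801	242	1404
Aldh1l1.1	227	1376	199	699	147	937	199	1108	201	683	309	1200
Pla2g7.1	33	244	38	268	43	182	61	202	38	121	39	182
Slc1a3.1	117	726	197	730	185	650	308	1097	253	786	182	473
Aldoc.1	70	321	102	406	119	396	90	297	123	361	98	365
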