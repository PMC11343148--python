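chr1	21390	21420	G00004.1	1	+
chr1	26598	26628	G00006.1	1	+
chr1	27321	27351	G00006.1	1	+
chr1	27632	27662	G00006.1	1	+
chr1	30764	30794	G00007.1	1	-
chr1	38209	38239	G00009.1	1	-
chr1	41678	41708	G00010.1	1	+
chr1	48441	48471	G00012.1	1	+
chr1	48604	48634	G00012.1	1	+
chr1	48631	48661	G00012.1	1	+
chr1	48692	48722	G00012.1	1	+
chr1	48698	48728	G00012.1	1	+
chr1	48780	48810	G00012.1	1	+
chr1	49579	49609	G00012.1	1	+
chr1	49598	49628	G00012.1	1	+
chr1	49661	49691	G00012.1	1	+
chr1	49734	49764	G00012.1	1	+
chr1	49852	49882	G00012.1	1	+
chr1	50240	50270	G00012.1	1	+
chr1	50626	50656	G00012.1	1	+
chr1	50900	50930	G00012.1	1	+
chr1	50980	51010	G00012.1	1	+
chr1	51084	51114	G00012.1	1	+
chr1	51089	51119	G00012.1	1	+
chr1	51113	51143	G00012.1	1	+
chr1	51143	51173	G00012.1	1	+
chr1	51316	51346	G00012.1	1	+
chr1	51321	51351	G00012.1	1	+
chr1	51504	51534	G00012.1	1	+
chr1	51663	51693	G00012.1	1	+
chr1	51855	51885	G00012.1	1	+
chr1	51879	51909	G00012.1	1	+
chr1	51911	51941	G00012.1	1	+
chr1	52221	52251	G00012.1	1	+
chr1	52332	52362	G00012.1	1	+
chr1	52434	52464	G00012.1	1	+
chr1	63343	63373	G00015.1	1	-
chr1	63592	63622	G00015.1	1	-
chr1	65902	65932	G00016.1	1	+
chr1	68006	68036	G00016.1	1	+
chr1	69007	69037	G00016.1	1	+
chr1	69819	69849	G00016.1	1	+
chr1	69921	69951	G00016.1	1	+
chr1	75200	75230	G00017.1	1	-
chr1	78088	78118	G00018.1	1	+
chr1	90063	90093	G00021.1	1	-
chr1	90978	91008	G00021.1	1	-
chr1	92725	92755	G00022.1	1	+
chr1	93520	93550	G00022.1	1	+
chr1	97000	97030	G00022.1	1	+
chr1	100694	100724	G00023.1	1	-
chr1	104117	104147	G00024.1	1	+
chr1	106355	106385	G00024.1	1	+
chr1	107914	107944	G00025.1	1	-
chr1	108610	108640	G00025.1	1	-
chr1	108659	108689	G00025.1	1	-
chr1	108706	108736	G00025.1	1	-
chr1	108740	108770	G00025.1	1	-
chr1	119348	119378	G00027.1	1	-
chr1	120749	120779	G00027.1	1	-
chr1	121025	121055	G00027.1	1	-
chr1	121435	121465	G00027.1	1	-
chr1	121873	121903	G00027.1	1	-
chr1	124258	124288	G00028.1	1	+
chr1	124922	124952	G00028.1	1	+
chr1	125653	125683	G00028.1	1	+
chr1	126465	126495	G00028.1	1	+
chr1	126482	126512	G00028.1	1	+
chr1	126686	126716	G00028.1	1	+
chr1	126939	126969	G00028.1	1	+
chr1	128296	128326	G00028.1	1	+
chr1	130725	130755	G00029.1	1	-
chr1	130739	130769	G00029.1	1	-
chr1	130750	130780	G00029.1	1	-
chr1	130880	130910	G00029.1	1	-
chr1	131833	131863	G00029.1	1	-
chr1	131882	131912	G00029.1	1	-
chr1	131890	131920	G00029.1	1	-
chr1	131986	132016	G00029.1	1	-
chr1	131991	132021	G00029.1	1	-
chr1	132054	132084	G00029.1	1	-
chr1	132103	132133	G00029.1	1	-
chr1	132113	132143	G00029.1	1	-
chr1	132263	132293	G00029.1	1	-
chr1	132315	132345	G00029.1	1	-
chr1	132530	132560	G00029.1	1	-
chr1	132737	132767	G00029.1	1	-
chr1	132899	132929	G00029.1	1	-
chr1	133038	133068	G00029.1	1	-
chr1	133155	133185	G00029.1	1	-
chr1	133163	133193	G00029.1	1	-
chr1	133207	133237	G00029.1	1	-
chr1	133324	133354	G00029.1	1	-
chr1	138491	138521	G00031.1	1	-
chr1	142068	142098	G00031.1	1	-
chr1	144479	144509	G00032.1	1	+
chr1	145991	146021	G00032.1	1	+
chr1	146221	146251	G00032.1	1	+
chr1	146303	146333	G00032.1	1	+
chr1	152635	152665	G00034.1	1	+
chr1	169335	169365	G00037.1	1	-
chr1	174222	174252	G00038.1	1	+
chr1	197445	197475	G00043.1	1	-
chr1	197747	197777	G00043.1	1	-
chr1	198037	198067	G00043.1	1	-
chr1	198831	198861	G00043.1	1	-
chr1	199885	199915	G00043.1	1	-
chr1	201588	201618	G00044.1	1	+
chr1	202521	202551	G00044.1	1	+
chr1	203209	203239	G00044.1	1	+
chr1	203251	203281	G00044.1	1	+
chr1	203291	203321	G00044.1	1	+
chr1	207142	207172	G00045.1	1	-
chr1	219202	219232	G00047.1	1	-
chr1	219462	219492	G00047.1	1	-
chr1	224022	224052	G00048.1	1	+
chr1	224094	224124	G00048.1	1	+
chr1	226782	226812	G00049.1	1	-
chr1	227650	227680	G00049.1	1	-
chr1	227820	227850	G00049.1	1	-
chr1	227999	228029	G00049.1	1	-
chr1	228201	228231	G00049.1	1	-
chr1	230280	230310	Neurod6.1	1	+
chr1	230418	230448	Neurod6.1	1	+
chr1	230515	230545	Neurod6.1	1	+
chr1	231297	231327	Neurod6.1	1	+
chr1	231304	231334	Neurod6.1	1	+
chr1	233121	233151	Neurod6.1	1	+
chr1	233363	233393	Neurod6.1	1	+
chr1	235218	235248	Camk2a.1	1	-
chr1	239924	239954	Rbfox3.1	1	+
chr1	239955	239985	Rbfox3.1	1	+
chr1	240199	240229	Rbfox3.1	1	+
chr1	241370	241400	Rbfox3.1	1	+
chr1	241621	241651	Rbfox3.1	1	+
chr1	246987	247017	Snap25.1	1	-
chr1	250645	250675	Nrgn.1	1	+
chr1	252550	252580	Hpca.1	1	-
chr1	252830	252860	Hpca.1	1	-
chr1	278978	279008	Calb2.1	1	+
chr1	279572	279602	Calb2.1	1	+
chr1	281159	281189	Calb2.1	1	+
chr1	281264	281294	Calb2.1	1	+
chr1	282372	282402	Calb2.1	1	+
chr1	326039	326069	Aqp4.1	1	+
chr1	329526	329556	Aldh1l1.1	1	-
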