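chr1	3831	3861	G00000.1	1	+
chr1	21127	21157	G00004.1	1	+
chr1	22026	22056	G00004.1	1	+
chr1	24798	24828	G00005.1	1	-
chr1	26584	26614	G00006.1	1	+
chr1	27363	27393	G00006.1	1	+
chr1	27731	27761	G00006.1	1	+
chr1	30612	30642	G00007.1	1	-
chr1	38063	38093	G00009.1	1	-
chr1	48033	48063	G00012.1	1	+
chr1	48494	48524	G00012.1	1	+
chr1	48788	48818	G00012.1	1	+
chr1	48897	48927	G00012.1	1	+
chr1	49468	49498	G00012.1	1	+
chr1	49502	49532	G00012.1	1	+
chr1	49506	49536	G00012.1	1	+
chr1	49563	49593	G00012.1	1	+
chr1	49639	49669	G00012.1	1	+
chr1	49655	49685	G00012.1	1	+
chr1	49668	49698	G00012.1	1	+
chr1	49684	49714	G00012.1	1	+
chr1	49812	49842	G00012.1	1	+
chr1	50481	50511	G00012.1	1	+
chr1	50652	50682	G00012.1	1	+
chr1	50657	50687	G00012.1	1	+
chr1	50906	50936	G00012.1	1	+
chr1	50981	51011	G00012.1	1	+
chr1	50993	51023	G00012.1	1	+
chr1	51098	51128	G00012.1	1	+
chr1	51161	51191	G00012.1	1	+
chr1	51326	51356	G00012.1	1	+
chr1	51337	51367	G00012.1	1	+
chr1	51363	51393	G00012.1	1	+
chr1	51404	51434	G00012.1	1	+
chr1	51542	51572	G00012.1	1	+
chr1	51630	51660	G00012.1	1	+
chr1	51725	51755	G00012.1	1	+
chr1	51737	51767	G00012.1	1	+
chr1	51847	51877	G00012.1	1	+
chr1	52223	52253	G00012.1	1	+
chr1	52245	52275	G00012.1	1	+
chr1	52355	52385	G00012.1	1	+
chr1	52409	52439	G00012.1	1	+
chr1	52531	52561	G00012.1	1	+
chr1	62893	62923	G00015.1	1	-
chr1	63288	63318	G00015.1	1	-
chr1	63717	63747	G00015.1	1	-
chr1	69242	69272	G00016.1	1	+
chr1	70129	70159	G00016.1	1	+
chr1	70962	70992	G00016.1	1	+
chr1	74188	74218	G00017.1	1	-
chr1	74747	74777	G00017.1	1	-
chr1	78145	78175	G00018.1	1	+
chr1	79936	79966	G00018.1	1	+
chr1	90633	90663	G00021.1	1	-
chr1	90835	90865	G00021.1	1	-
chr1	90958	90988	G00021.1	1	-
chr1	90982	91012	G00021.1	1	-
chr1	92909	92939	G00022.1	1	+
chr1	93407	93437	G00022.1	1	+
chr1	95908	95938	G00022.1	1	+
chr1	106253	106283	G00024.1	1	+
chr1	107913	107943	G00025.1	1	-
chr1	108023	108053	G00025.1	1	-
chr1	108649	108679	G00025.1	1	-
chr1	108817	108847	G00025.1	1	-
chr1	108880	108910	G00025.1	1	-
chr1	108908	108938	G00025.1	1	-
chr1	117881	117911	G00027.1	1	-
chr1	119580	119610	G00027.1	1	-
chr1	120153	120183	G00027.1	1	-
chr1	120276	120306	G00027.1	1	-
chr1	121612	121642	G00027.1	1	-
chr1	121681	121711	G00027.1	1	-
chr1	122286	122316	G00027.1	1	-
chr1	124201	124231	G00028.1	1	+
chr1	125645	125675	G00028.1	1	+
chr1	125950	125980	G00028.1	1	+
chr1	126972	127002	G00028.1	1	+
chr1	127128	127158	G00028.1	1	+
chr1	127353	127383	G00028.1	1	+
chr1	127623	127653	G00028.1	1	+
chr1	130708	130738	G00029.1	1	-
chr1	131968	131998	G00029.1	1	-
chr1	132038	132068	G00029.1	1	-
chr1	132784	132814	G00029.1	1	-
chr1	132984	133014	G00029.1	1	-
chr1	133014	133044	G00029.1	1	-
chr1	133023	133053	G00029.1	1	-
chr1	133065	133095	G00029.1	1	-
chr1	133188	133218	G00029.1	1	-
chr1	133204	133234	G00029.1	1	-
chr1	138145	138175	G00031.1	1	-
chr1	138906	138936	G00031.1	1	-
chr1	141050	141080	G00031.1	1	-
chr1	141133	141163	G00031.1	1	-
chr1	145835	145865	G00032.1	1	+
chr1	146257	146287	G00032.1	1	+
chr1	146691	146721	G00032.1	1	+
chr1	146767	146797	G00032.1	1	+
chr1	147107	147137	G00032.1	1	+
chr1	151633	151663	G00034.1	1	+
chr1	170428	170458	G00037.1	1	-
chr1	174212	174242	G00038.1	1	+
chr1	175243	175273	G00038.1	1	+
chr1	178894	178924	G00039.1	1	-
chr1	196857	196887	G00043.1	1	-
chr1	197047	197077	G00043.1	1	-
chr1	197666	197696	G00043.1	1	-
chr1	198315	198345	G00043.1	1	-
chr1	198556	198586	G00043.1	1	-
chr1	199088	199118	G00043.1	1	-
chr1	201775	201805	G00044.1	1	+
chr1	202540	202570	G00044.1	1	+
chr1	202690	202720	G00044.1	1	+
chr1	203365	203395	G00044.1	1	+
chr1	203653	203683	G00044.1	1	+
chr1	217176	217206	G00047.1	1	-
chr1	217275	217305	G00047.1	1	-
chr1	219042	219072	G00047.1	1	-
chr1	223120	223150	G00048.1	1	+
chr1	224544	224574	G00048.1	1	+
chr1	226794	226824	G00049.1	1	-
chr1	226894	226924	G00049.1	1	-
chr1	227791	227821	G00049.1	1	-
chr1	230280	230310	Neurod6.1	1	+
chr1	230287	230317	Neurod6.1	1	+
chr1	230486	230516	Neurod6.1	1	+
chr1	230583	230613	Neurod6.1	1	+
chr1	231742	231772	Neurod6.1	1	+
chr1	232048	232078	Neurod6.1	1	+
chr1	236505	236535	Camk2a.1	1	-
chr1	240180	240210	Rbfox3.1	1	+
chr1	241756	241786	Rbfox3.1	1	+
chr1	241831	241861	Rbfox3.1	1	+
chr1	242160	242190	Rbfox3.1	1	+
chr1	242318	242348	Rbfox3.1	1	+
chr1	242430	242460	Rbfox3.1	1	+
chr1	244562	244592	Snap25.1	1	-
chr1	249292	249322	Nrgn.1	1	+
chr1	252766	252796	Hpca.1	1	-
chr1	279421	279451	Calb2.1	1	+
chr1	281358	281388	Calb2.1	1	+
chr1	281879	281909	Calb2.1	1	+
chr1	282151	282181	Calb2.1	1	+
chr1	282412	282442	Calb2.1	1	+
chr1	344381	344411	Slc1a3.1	1	-
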