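chr1	23815	23845	G00005.1	1	-
chr1	36117	36147	G00009.1	1	-
chr1	37646	37676	G00009.1	1	-
chr1	47940	47970	G00012.1	1	+
chr1	47942	47972	G00012.1	1	+
chr1	48015	48045	G00012.1	1	+
chr1	48098	48128	G00012.1	1	+
chr1	48103	48133	G00012.1	1	+
chr1	48110	48140	G00012.1	1	+
chr1	48180	48210	G00012.1	1	+
chr1	48190	48220	G00012.1	1	+
chr1	48191	48221	G00012.1	1	+
chr1	48234	48264	G00012.1	1	+
chr1	48249	48279	G00012.1	1	+
chr1	48256	48286	G00012.1	1	+
chr1	48331	48361	G00012.1	1	+
chr1	48344	48374	G00012.1	1	+
chr1	48373	48403	G00012.1	1	+
chr1	48414	48444	G00012.1	1	+
chr1	48446	48476	G00012.1	1	+
chr1	48506	48536	G00012.1	1	+
chr1	48558	48588	G00012.1	1	+
chr1	48600	48630	G00012.1	1	+
chr1	48602	48632	G00012.1	1	+
chr1	48620	48650	G00012.1	1	+
chr1	48636	48666	G00012.1	1	+
chr1	48670	48700	G00012.1	1	+
chr1	48719	48749	G00012.1	1	+
chr1	48722	48752	G00012.1	1	+
chr1	48872	48902	G00012.1	1	+
chr1	48900	48930	G00012.1	1	+
chr1	48905	48935	G00012.1	1	+
chr1	48963	48993	G00012.1	1	+
chr1	49638	49668	G00012.1	1	+
chr1	49681	49711	G00012.1	1	+
chr1	49698	49728	G00012.1	1	+
chr1	49770	49800	G00012.1	1	+
chr1	49793	49823	G00012.1	1	+
chr1	49805	49835	G00012.1	1	+
chr1	49816	49846	G00012.1	1	+
chr1	49845	49875	G00012.1	1	+
chr1	49851	49881	G00012.1	1	+
chr1	49932	49962	G00012.1	1	+
chr1	50046	50076	G00012.1	1	+
chr1	50050	50080	G00012.1	1	+
chr1	50067	50097	G00012.1	1	+
chr1	50076	50106	G00012.1	1	+
chr1	50152	50182	G00012.1	1	+
chr1	50157	50187	G00012.1	1	+
chr1	50203	50233	G00012.1	1	+
chr1	50236	50266	G00012.1	1	+
chr1	50302	50332	G00012.1	1	+
chr1	50339	50369	G00012.1	1	+
chr1	50359	50389	G00012.1	1	+
chr1	50386	50416	G00012.1	1	+
chr1	50408	50438	G00012.1	1	+
chr1	50435	50465	G00012.1	1	+
chr1	50446	50476	G00012.1	1	+
chr1	50448	50478	G00012.1	1	+
chr1	50476	50506	G00012.1	1	+
chr1	50560	50590	G00012.1	1	+
chr1	50686	50716	G00012.1	1	+
chr1	50753	50783	G00012.1	1	+
chr1	50760	50790	G00012.1	1	+
chr1	50769	50799	G00012.1	1	+
chr1	50770	50800	G00012.1	1	+
chr1	50784	50814	G00012.1	1	+
chr1	50852	50882	G00012.1	1	+
chr1	50854	50884	G00012.1	1	+
chr1	50868	50898	G00012.1	1	+
chr1	50892	50922	G00012.1	1	+
chr1	50933	50963	G00012.1	1	+
chr1	50965	50995	G00012.1	1	+
chr1	50982	51012	G00012.1	1	+
chr1	51229	51259	G00012.1	1	+
chr1	51259	51289	G00012.1	1	+
chr1	51328	51358	G00012.1	1	+
chr1	51421	51451	G00012.1	1	+
chr1	51461	51491	G00012.1	1	+
chr1	51467	51497	G00012.1	1	+
chr1	51483	51513	G00012.1	1	+
chr1	51521	51551	G00012.1	1	+
chr1	51605	51635	G00012.1	1	+
chr1	51622	51652	G00012.1	1	+
chr1	51630	51660	G00012.1	1	+
chr1	51768	51798	G00012.1	1	+
chr1	51821	51851	G00012.1	1	+
chr1	51860	51890	G00012.1	1	+
chr1	51905	51935	G00012.1	1	+
chr1	51919	51949	G00012.1	1	+
chr1	51956	51986	G00012.1	1	+
chr1	51980	52010	G00012.1	1	+
chr1	52052	52082	G00012.1	1	+
chr1	52058	52088	G00012.1	1	+
chr1	52066	52096	G00012.1	1	+
chr1	52105	52135	G00012.1	1	+
chr1	52150	52180	G00012.1	1	+
chr1	52150	52180	G00012.1	1	+
chr1	52257	52287	G00012.1	1	+
chr1	52306	52336	G00012.1	1	+
chr1	52478	52508	G00012.1	1	+
chr1	52482	52512	G00012.1	1	+
chr1	52512	52542	G00012.1	1	+
chr1	63560	63590	G00015.1	1	-
chr1	66508	66538	G00016.1	1	+
chr1	74889	74919	G00017.1	1	-
chr1	81870	81900	G00018.1	1	+
chr1	91009	91039	G00021.1	1	-
chr1	94807	94837	G00022.1	1	+
chr1	108774	108804	G00025.1	1	-
chr1	121351	121381	G00027.1	1	-
chr1	130745	130775	G00029.1	1	-
chr1	131742	131772	G00029.1	1	-
chr1	131982	132012	G00029.1	1	-
chr1	132066	132096	G00029.1	1	-
chr1	132236	132266	G00029.1	1	-
chr1	132256	132286	G00029.1	1	-
chr1	132548	132578	G00029.1	1	-
chr1	133167	133197	G00029.1	1	-
chr1	133353	133383	G00029.1	1	-
chr1	139513	139543	G00031.1	1	-
chr1	146518	146548	G00032.1	1	+
chr1	146592	146622	G00032.1	1	+
chr1	191143	191173	G00042.1	1	+
chr1	195870	195900	G00043.1	1	-
chr1	199135	199165	G00043.1	1	-
chr1	199747	199777	G00043.1	1	-
chr1	202710	202740	G00044.1	1	+
chr1	217146	217176	G00047.1	1	-
chr1	218515	218545	G00047.1	1	-
chr1	219109	219139	G00047.1	1	-
chr1	219608	219638	G00047.1	1	-
chr1	220101	220131	G00047.1	1	-
chr1	224060	224090	G00048.1	1	+
chr1	230620	230650	Neurod6.1	1	+
chr1	231569	231599	Neurod6.1	1	+
chr1	232365	232395	Neurod6.1	1	+
chr1	233228	233258	Neurod6.1	1	+
chr1	241011	241041	Rbfox3.1	1	+
chr1	241858	241888	Rbfox3.1	1	+
chr1	253775	253805	Hpca.1	1	-
chr1	279451	279481	Calb2.1	1	+
chr1	282235	282265	Calb2.1	1	+
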