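chr1	23757	23787	G00005.1	1	-
chr1	37233	37263	G00009.1	1	-
chr1	38156	38186	G00009.1	1	-
chr1	47935	47965	G00012.1	1	+
chr1	47953	47983	G00012.1	1	+
chr1	48018	48048	G00012.1	1	+
chr1	48069	48099	G00012.1	1	+
chr1	48075	48105	G00012.1	1	+
chr1	48100	48130	G00012.1	1	+
chr1	48108	48138	G00012.1	1	+
chr1	48139	48169	G00012.1	1	+
chr1	48220	48250	G00012.1	1	+
chr1	48236	48266	G00012.1	1	+
chr1	48346	48376	G00012.1	1	+
chr1	48357	48387	G00012.1	1	+
chr1	48367	48397	G00012.1	1	+
chr1	48422	48452	G00012.1	1	+
chr1	48453	48483	G00012.1	1	+
chr1	48493	48523	G00012.1	1	+
chr1	48521	48551	G00012.1	1	+
chr1	48533	48563	G00012.1	1	+
chr1	48538	48568	G00012.1	1	+
chr1	48578	48608	G00012.1	1	+
chr1	48609	48639	G00012.1	1	+
chr1	48669	48699	G00012.1	1	+
chr1	48681	48711	G00012.1	1	+
chr1	48683	48713	G00012.1	1	+
chr1	48691	48721	G00012.1	1	+
chr1	48698	48728	G00012.1	1	+
chr1	48790	48820	G00012.1	1	+
chr1	48852	48882	G00012.1	1	+
chr1	48870	48900	G00012.1	1	+
chr1	48936	48966	G00012.1	1	+
chr1	48956	48986	G00012.1	1	+
chr1	48965	48995	G00012.1	1	+
chr1	49533	49563	G00012.1	1	+
chr1	49630	49660	G00012.1	1	+
chr1	49633	49663	G00012.1	1	+
chr1	49727	49757	G00012.1	1	+
chr1	49765	49795	G00012.1	1	+
chr1	49790	49820	G00012.1	1	+
chr1	49805	49835	G00012.1	1	+
chr1	49812	49842	G00012.1	1	+
chr1	49829	49859	G00012.1	1	+
chr1	49842	49872	G00012.1	1	+
chr1	49852	49882	G00012.1	1	+
chr1	49879	49909	G00012.1	1	+
chr1	49954	49984	G00012.1	1	+
chr1	49981	50011	G00012.1	1	+
chr1	50042	50072	G00012.1	1	+
chr1	50120	50150	G00012.1	1	+
chr1	50126	50156	G00012.1	1	+
chr1	50206	50236	G00012.1	1	+
chr1	50217	50247	G00012.1	1	+
chr1	50238	50268	G00012.1	1	+
chr1	50249	50279	G00012.1	1	+
chr1	50266	50296	G00012.1	1	+
chr1	50368	50398	G00012.1	1	+
chr1	50392	50422	G00012.1	1	+
chr1	50417	50447	G00012.1	1	+
chr1	50443	50473	G00012.1	1	+
chr1	50543	50573	G00012.1	1	+
chr1	50586	50616	G00012.1	1	+
chr1	50601	50631	G00012.1	1	+
chr1	50650	50680	G00012.1	1	+
chr1	50696	50726	G00012.1	1	+
chr1	50701	50731	G00012.1	1	+
chr1	50837	50867	G00012.1	1	+
chr1	50861	50891	G00012.1	1	+
chr1	50882	50912	G00012.1	1	+
chr1	50923	50953	G00012.1	1	+
chr1	50934	50964	G00012.1	1	+
chr1	50946	50976	G00012.1	1	+
chr1	50963	50993	G00012.1	1	+
chr1	50996	51026	G00012.1	1	+
chr1	51041	51071	G00012.1	1	+
chr1	51113	51143	G00012.1	1	+
chr1	51145	51175	G00012.1	1	+
chr1	51163	51193	G00012.1	1	+
chr1	51215	51245	G00012.1	1	+
chr1	51224	51254	G00012.1	1	+
chr1	51245	51275	G00012.1	1	+
chr1	51253	51283	G00012.1	1	+
chr1	51283	51313	G00012.1	1	+
chr1	51285	51315	G00012.1	1	+
chr1	51287	51317	G00012.1	1	+
chr1	51287	51317	G00012.1	1	+
chr1	51319	51349	G00012.1	1	+
chr1	51367	51397	G00012.1	1	+
chr1	51431	51461	G00012.1	1	+
chr1	51467	51497	G00012.1	1	+
chr1	51489	51519	G00012.1	1	+
chr1	51503	51533	G00012.1	1	+
chr1	51575	51605	G00012.1	1	+
chr1	51684	51714	G00012.1	1	+
chr1	51723	51753	G00012.1	1	+
chr1	51731	51761	G00012.1	1	+
chr1	51771	51801	G00012.1	1	+
chr1	51773	51803	G00012.1	1	+
chr1	51788	51818	G00012.1	1	+
chr1	51870	51900	G00012.1	1	+
chr1	51914	51944	G00012.1	1	+
chr1	51970	52000	G00012.1	1	+
chr1	51981	52011	G00012.1	1	+
chr1	51999	52029	G00012.1	1	+
chr1	52007	52037	G00012.1	1	+
chr1	52054	52084	G00012.1	1	+
chr1	52063	52093	G00012.1	1	+
chr1	52075	52105	G00012.1	1	+
chr1	52106	52136	G00012.1	1	+
chr1	52108	52138	G00012.1	1	+
chr1	52111	52141	G00012.1	1	+
chr1	52159	52189	G00012.1	1	+
chr1	52189	52219	G00012.1	1	+
chr1	52195	52225	G00012.1	1	+
chr1	52227	52257	G00012.1	1	+
chr1	52311	52341	G00012.1	1	+
chr1	52350	52380	G00012.1	1	+
chr1	52352	52382	G00012.1	1	+
chr1	52425	52455	G00012.1	1	+
chr1	52433	52463	G00012.1	1	+
chr1	52435	52465	G00012.1	1	+
chr1	52466	52496	G00012.1	1	+
chr1	52486	52516	G00012.1	1	+
chr1	52541	52571	G00012.1	1	+
chr1	52549	52579	G00012.1	1	+
chr1	52551	52581	G00012.1	1	+
chr1	69206	69236	G00016.1	1	+
chr1	77858	77888	G00018.1	1	+
chr1	90845	90875	G00021.1	1	-
chr1	108902	108932	G00025.1	1	-
chr1	119572	119602	G00027.1	1	-
chr1	131047	131077	G00029.1	1	-
chr1	132790	132820	G00029.1	1	-
chr1	138469	138499	G00031.1	1	-
chr1	144673	144703	G00032.1	1	+
chr1	193249	193279	G00042.1	1	+
chr1	195517	195547	G00043.1	1	-
chr1	203699	203729	G00044.1	1	+
chr1	217201	217231	G00047.1	1	-
chr1	217338	217368	G00047.1	1	-
chr1	219838	219868	G00047.1	1	-
chr1	224170	224200	G00048.1	1	+
chr1	228094	228124	G00049.1	1	-
chr1	230690	230720	Neurod6.1	1	+
chr1	241503	241533	Rbfox3.1	1	+
chr1	241568	241598	Rbfox3.1	1	+
chr1	241581	241611	Rbfox3.1	1	+
chr1	280536	280566	Calb2.1	1	+
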