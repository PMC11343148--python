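chr1	1359	1389	G00000.1	1	+
chr1	21681	21711	G00004.1	1	+
chr1	27354	27384	G00006.1	1	+
chr1	27409	27439	G00006.1	1	+
chr1	28084	28114	G00006.1	1	+
chr1	28101	28131	G00006.1	1	+
chr1	31452	31482	G00007.1	1	-
chr1	41835	41865	G00010.1	1	+
chr1	48268	48298	G00012.1	1	+
chr1	48295	48325	G00012.1	1	+
chr1	48673	48703	G00012.1	1	+
chr1	48873	48903	G00012.1	1	+
chr1	48875	48905	G00012.1	1	+
chr1	48926	48956	G00012.1	1	+
chr1	50098	50128	G00012.1	1	+
chr1	50112	50142	G00012.1	1	+
chr1	50258	50288	G00012.1	1	+
chr1	50346	50376	G00012.1	1	+
chr1	50611	50641	G00012.1	1	+
chr1	50704	50734	G00012.1	1	+
chr1	50822	50852	G00012.1	1	+
chr1	51075	51105	G00012.1	1	+
chr1	51232	51262	G00012.1	1	+
chr1	51272	51302	G00012.1	1	+
chr1	51292	51322	G00012.1	1	+
chr1	51430	51460	G00012.1	1	+
chr1	51496	51526	G00012.1	1	+
chr1	52092	52122	G00012.1	1	+
chr1	52153	52183	G00012.1	1	+
chr1	52275	52305	G00012.1	1	+
chr1	52283	52313	G00012.1	1	+
chr1	52288	52318	G00012.1	1	+
chr1	52304	52334	G00012.1	1	+
chr1	52482	52512	G00012.1	1	+
chr1	52513	52543	G00012.1	1	+
chr1	62259	62289	G00015.1	1	-
chr1	66245	66275	G00016.1	1	+
chr1	66278	66308	G00016.1	1	+
chr1	68948	68978	G00016.1	1	+
chr1	73357	73387	G00017.1	1	-
chr1	75336	75366	G00017.1	1	-
chr1	75776	75806	G00017.1	1	-
chr1	78226	78256	G00018.1	1	+
chr1	79944	79974	G00018.1	1	+
chr1	80942	80972	G00018.1	1	+
chr1	90629	90659	G00021.1	1	-
chr1	90735	90765	G00021.1	1	-
chr1	90930	90960	G00021.1	1	-
chr1	90952	90982	G00021.1	1	-
chr1	95563	95593	G00022.1	1	+
chr1	96801	96831	G00022.1	1	+
chr1	97050	97080	G00022.1	1	+
chr1	103849	103879	G00024.1	1	+
chr1	108561	108591	G00025.1	1	-
chr1	108615	108645	G00025.1	1	-
chr1	108755	108785	G00025.1	1	-
chr1	117385	117415	G00027.1	1	-
chr1	118963	118993	G00027.1	1	-
chr1	120564	120594	G00027.1	1	-
chr1	121177	121207	G00027.1	1	-
chr1	121830	121860	G00027.1	1	-
chr1	122193	122223	G00027.1	1	-
chr1	124073	124103	G00028.1	1	+
chr1	126128	126158	G00028.1	1	+
chr1	126598	126628	G00028.1	1	+
chr1	127055	127085	G00028.1	1	+
chr1	128024	128054	G00028.1	1	+
chr1	128567	128597	G00028.1	1	+
chr1	130790	130820	G00029.1	1	-
chr1	130822	130852	G00029.1	1	-
chr1	130900	130930	G00029.1	1	-
chr1	131096	131126	G00029.1	1	-
chr1	131778	131808	G00029.1	1	-
chr1	131785	131815	G00029.1	1	-
chr1	131899	131929	G00029.1	1	-
chr1	131951	131981	G00029.1	1	-
chr1	132509	132539	G00029.1	1	-
chr1	132523	132553	G00029.1	1	-
chr1	132677	132707	G00029.1	1	-
chr1	132683	132713	G00029.1	1	-
chr1	133196	133226	G00029.1	1	-
chr1	133229	133259	G00029.1	1	-
chr1	133337	133367	G00029.1	1	-
chr1	133380	133410	G00029.1	1	-
chr1	133428	133458	G00029.1	1	-
chr1	138314	138344	G00031.1	1	-
chr1	140144	140174	G00031.1	1	-
chr1	145847	145877	G00032.1	1	+
chr1	145907	145937	G00032.1	1	+
chr1	146441	146471	G00032.1	1	+
chr1	146443	146473	G00032.1	1	+
chr1	151763	151793	G00034.1	1	+
chr1	152832	152862	G00034.1	1	+
chr1	172956	172986	G00038.1	1	+
chr1	175185	175215	G00038.1	1	+
chr1	190583	190613	G00042.1	1	+
chr1	195357	195387	G00043.1	1	-
chr1	195774	195804	G00043.1	1	-
chr1	197263	197293	G00043.1	1	-
chr1	197777	197807	G00043.1	1	-
chr1	197884	197914	G00043.1	1	-
chr1	198042	198072	G00043.1	1	-
chr1	199303	199333	G00043.1	1	-
chr1	201518	201548	G00044.1	1	+
chr1	201778	201808	G00044.1	1	+
chr1	203784	203814	G00044.1	1	+
chr1	204027	204057	G00044.1	1	+
chr1	216683	216713	G00047.1	1	-
chr1	219403	219433	G00047.1	1	-
chr1	224541	224571	G00048.1	1	+
chr1	225112	225142	G00048.1	1	+
chr1	226992	227022	G00049.1	1	-
chr1	228199	228229	G00049.1	1	-
chr1	230068	230098	Neurod6.1	1	+
chr1	230306	230336	Neurod6.1	1	+
chr1	230391	230421	Neurod6.1	1	+
chr1	230483	230513	Neurod6.1	1	+
chr1	231415	231445	Neurod6.1	1	+
chr1	231516	231546	Neurod6.1	1	+
chr1	231650	231680	Neurod6.1	1	+
chr1	231682	231712	Neurod6.1	1	+
chr1	231869	231899	Neurod6.1	1	+
chr1	232661	232691	Neurod6.1	1	+
chr1	232841	232871	Neurod6.1	1	+
chr1	232916	232946	Neurod6.1	1	+
chr1	233352	233382	Neurod6.1	1	+
chr1	234916	234946	Camk2a.1	1	-
chr1	240863	240893	Rbfox3.1	1	+
chr1	241739	241769	Rbfox3.1	1	+
chr1	241925	241955	Rbfox3.1	1	+
chr1	242187	242217	Rbfox3.1	1	+
chr1	244587	244617	Snap25.1	1	-
chr1	245517	245547	Snap25.1	1	-
chr1	250009	250039	Nrgn.1	1	+
chr1	253607	253637	Hpca.1	1	-
chr1	253795	253825	Hpca.1	1	-
chr1	254220	254250	Hpca.1	1	-
chr1	278760	278790	Calb2.1	1	+
chr1	279576	279606	Calb2.1	1	+
chr1	280973	281003	Calb2.1	1	+
chr1	281984	282014	Calb2.1	1	+
chr1	282353	282383	Calb2.1	1	+
chr1	323721	323751	Aqp4.1	1	+
chr1	331041	331071	Aldh1l1.1	1	-
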