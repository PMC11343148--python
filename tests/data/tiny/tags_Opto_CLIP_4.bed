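chr1	24727	24757	G00005.1	1	-
chr1	38167	38197	G00009.1	1	-
chr1	47936	47966	G00012.1	1	+
chr1	47946	47976	G00012.1	1	+
chr1	47962	47992	G00012.1	1	+
chr1	48077	48107	G00012.1	1	+
chr1	48095	48125	G00012.1	1	+
chr1	48109	48139	G00012.1	1	+
chr1	48166	48196	G00012.1	1	+
chr1	48172	48202	G00012.1	1	+
chr1	48215	48245	G00012.1	1	+
chr1	48231	48261	G00012.1	1	+
chr1	48245	48275	G00012.1	1	+
chr1	48272	48302	G00012.1	1	+
chr1	48348	48378	G00012.1	1	+
chr1	48451	48481	G00012.1	1	+
chr1	48499	48529	G00012.1	1	+
chr1	48512	48542	G00012.1	1	+
chr1	48550	48580	G00012.1	1	+
chr1	48600	48630	G00012.1	1	+
chr1	48602	48632	G00012.1	1	+
chr1	48620	48650	G00012.1	1	+
chr1	48707	48737	G00012.1	1	+
chr1	48763	48793	G00012.1	1	+
chr1	48774	48804	G00012.1	1	+
chr1	48855	48885	G00012.1	1	+
chr1	48891	48921	G00012.1	1	+
chr1	49475	49505	G00012.1	1	+
chr1	49494	49524	G00012.1	1	+
chr1	49539	49569	G00012.1	1	+
chr1	49573	49603	G00012.1	1	+
chr1	49635	49665	G00012.1	1	+
chr1	49672	49702	G00012.1	1	+
chr1	49683	49713	G00012.1	1	+
chr1	49698	49728	G00012.1	1	+
chr1	49719	49749	G00012.1	1	+
chr1	49728	49758	G00012.1	1	+
chr1	49784	49814	G00012.1	1	+
chr1	49940	49970	G00012.1	1	+
chr1	49956	49986	G00012.1	1	+
chr1	49981	50011	G00012.1	1	+
chr1	50015	50045	G00012.1	1	+
chr1	50054	50084	G00012.1	1	+
chr1	50075	50105	G00012.1	1	+
chr1	50102	50132	G00012.1	1	+
chr1	50105	50135	G00012.1	1	+
chr1	50123	50153	G00012.1	1	+
chr1	50175	50205	G00012.1	1	+
chr1	50234	50264	G00012.1	1	+
chr1	50285	50315	G00012.1	1	+
chr1	50319	50349	G00012.1	1	+
chr1	50366	50396	G00012.1	1	+
chr1	50452	50482	G00012.1	1	+
chr1	50496	50526	G00012.1	1	+
chr1	50547	50577	G00012.1	1	+
chr1	50570	50600	G00012.1	1	+
chr1	50610	50640	G00012.1	1	+
chr1	50616	50646	G00012.1	1	+
chr1	50655	50685	G00012.1	1	+
chr1	50664	50694	G00012.1	1	+
chr1	50674	50704	G00012.1	1	+
chr1	50729	50759	G00012.1	1	+
chr1	50751	50781	G00012.1	1	+
chr1	50759	50789	G00012.1	1	+
chr1	50785	50815	G00012.1	1	+
chr1	50792	50822	G00012.1	1	+
chr1	50820	50850	G00012.1	1	+
chr1	50823	50853	G00012.1	1	+
chr1	50851	50881	G00012.1	1	+
chr1	50895	50925	G00012.1	1	+
chr1	50946	50976	G00012.1	1	+
chr1	50963	50993	G00012.1	1	+
chr1	50981	51011	G00012.1	1	+
chr1	51003	51033	G00012.1	1	+
chr1	51084	51114	G00012.1	1	+
chr1	51254	51284	G00012.1	1	+
chr1	51273	51303	G00012.1	1	+
chr1	51283	51313	G00012.1	1	+
chr1	51337	51367	G00012.1	1	+
chr1	51359	51389	G00012.1	1	+
chr1	51383	51413	G00012.1	1	+
chr1	51388	51418	G00012.1	1	+
chr1	51401	51431	G00012.1	1	+
chr1	51431	51461	G00012.1	1	+
chr1	51477	51507	G00012.1	1	+
chr1	51480	51510	G00012.1	1	+
chr1	51527	51557	G00012.1	1	+
chr1	51623	51653	G00012.1	1	+
chr1	51686	51716	G00012.1	1	+
chr1	51708	51738	G00012.1	1	+
chr1	51883	51913	G00012.1	1	+
chr1	51914	51944	G00012.1	1	+
chr1	51922	51952	G00012.1	1	+
chr1	51947	51977	G00012.1	1	+
chr1	52045	52075	G00012.1	1	+
chr1	52056	52086	G00012.1	1	+
chr1	52179	52209	G00012.1	1	+
chr1	52227	52257	G00012.1	1	+
chr1	52310	52340	G00012.1	1	+
chr1	52314	52344	G00012.1	1	+
chr1	52316	52346	G00012.1	1	+
chr1	52343	52373	G00012.1	1	+
chr1	52390	52420	G00012.1	1	+
chr1	52458	52488	G00012.1	1	+
chr1	52474	52504	G00012.1	1	+
chr1	52480	52510	G00012.1	1	+
chr1	52527	52557	G00012.1	1	+
chr1	52556	52586	G00012.1	1	+
chr1	68265	68295	G00016.1	1	+
chr1	68414	68444	G00016.1	1	+
chr1	74265	74295	G00017.1	1	-
chr1	81676	81706	G00018.1	1	+
chr1	90644	90674	G00021.1	1	-
chr1	93453	93483	G00022.1	1	+
chr1	93509	93539	G00022.1	1	+
chr1	103833	103863	G00024.1	1	+
chr1	108058	108088	G00025.1	1	-
chr1	121059	121089	G00027.1	1	-
chr1	130707	130737	G00029.1	1	-
chr1	131138	131168	G00029.1	1	-
chr1	132964	132994	G00029.1	1	-
chr1	133039	133069	G00029.1	1	-
chr1	133348	133378	G00029.1	1	-
chr1	138723	138753	G00031.1	1	-
chr1	144555	144585	G00032.1	1	+
chr1	145572	145602	G00032.1	1	+
chr1	189176	189206	G00042.1	1	+
chr1	189483	189513	G00042.1	1	+
chr1	193098	193128	G00042.1	1	+
chr1	199840	199870	G00043.1	1	-
chr1	202530	202560	G00044.1	1	+
chr1	203268	203298	G00044.1	1	+
chr1	218148	218178	G00047.1	1	-
chr1	218269	218299	G00047.1	1	-
chr1	220779	220809	G00047.1	1	-
chr1	227629	227659	G00049.1	1	-
chr1	230147	230177	Neurod6.1	1	+
chr1	230319	230349	Neurod6.1	1	+
chr1	231656	231686	Neurod6.1	1	+
chr1	231938	231968	Neurod6.1	1	+
chr1	232172	232202	Neurod6.1	1	+
chr1	241166	241196	Rbfox3.1	1	+
chr1	250724	250754	Nrgn.1	1	+
chr1	254772	254802	Hpca.1	1	-
chr1	279378	279408	Calb2.1	1	+
chr1	282749	282779	Calb2.1	1	+
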