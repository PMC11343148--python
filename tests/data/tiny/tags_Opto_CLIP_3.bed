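chr1	23774	23804	G00005.1	1	-
chr1	37311	37341	G00009.1	1	-
chr1	47943	47973	G00012.1	1	+
chr1	47951	47981	G00012.1	1	+
chr1	47954	47984	G00012.1	1	+
chr1	47969	47999	G00012.1	1	+
chr1	48015	48045	G00012.1	1	+
chr1	48069	48099	G00012.1	1	+
chr1	48077	48107	G00012.1	1	+
chr1	48095	48125	G00012.1	1	+
chr1	48107	48137	G00012.1	1	+
chr1	48133	48163	G00012.1	1	+
chr1	48138	48168	G00012.1	1	+
chr1	48168	48198	G00012.1	1	+
chr1	48205	48235	G00012.1	1	+
chr1	48250	48280	G00012.1	1	+
chr1	48264	48294	G00012.1	1	+
chr1	48292	48322	G00012.1	1	+
chr1	48342	48372	G00012.1	1	+
chr1	48350	48380	G00012.1	1	+
chr1	48394	48424	G00012.1	1	+
chr1	48421	48451	G00012.1	1	+
chr1	48422	48452	G00012.1	1	+
chr1	48473	48503	G00012.1	1	+
chr1	48492	48522	G00012.1	1	+
chr1	48510	48540	G00012.1	1	+
chr1	48670	48700	G00012.1	1	+
chr1	48680	48710	G00012.1	1	+
chr1	48777	48807	G00012.1	1	+
chr1	48824	48854	G00012.1	1	+
chr1	48838	48868	G00012.1	1	+
chr1	48851	48881	G00012.1	1	+
chr1	48888	48918	G00012.1	1	+
chr1	48916	48946	G00012.1	1	+
chr1	49473	49503	G00012.1	1	+
chr1	49479	49509	G00012.1	1	+
chr1	49591	49621	G00012.1	1	+
chr1	49673	49703	G00012.1	1	+
chr1	49757	49787	G00012.1	1	+
chr1	49788	49818	G00012.1	1	+
chr1	49844	49874	G00012.1	1	+
chr1	49901	49931	G00012.1	1	+
chr1	49931	49961	G00012.1	1	+
chr1	50001	50031	G00012.1	1	+
chr1	50094	50124	G00012.1	1	+
chr1	50108	50138	G00012.1	1	+
chr1	50109	50139	G00012.1	1	+
chr1	50120	50150	G00012.1	1	+
chr1	50156	50186	G00012.1	1	+
chr1	50183	50213	G00012.1	1	+
chr1	50195	50225	G00012.1	1	+
chr1	50214	50244	G00012.1	1	+
chr1	50303	50333	G00012.1	1	+
chr1	50317	50347	G00012.1	1	+
chr1	50391	50421	G00012.1	1	+
chr1	50407	50437	G00012.1	1	+
chr1	50420	50450	G00012.1	1	+
chr1	50424	50454	G00012.1	1	+
chr1	50441	50471	G00012.1	1	+
chr1	50447	50477	G00012.1	1	+
chr1	50489	50519	G00012.1	1	+
chr1	50490	50520	G00012.1	1	+
chr1	50515	50545	G00012.1	1	+
chr1	50565	50595	G00012.1	1	+
chr1	50654	50684	G00012.1	1	+
chr1	50667	50697	G00012.1	1	+
chr1	50711	50741	G00012.1	1	+
chr1	50729	50759	G00012.1	1	+
chr1	50729	50759	G00012.1	1	+
chr1	50768	50798	G00012.1	1	+
chr1	50778	50808	G00012.1	1	+
chr1	50786	50816	G00012.1	1	+
chr1	50800	50830	G00012.1	1	+
chr1	50868	50898	G00012.1	1	+
chr1	50875	50905	G00012.1	1	+
chr1	50914	50944	G00012.1	1	+
chr1	50922	50952	G00012.1	1	+
chr1	50942	50972	G00012.1	1	+
chr1	50958	50988	G00012.1	1	+
chr1	50963	50993	G00012.1	1	+
chr1	51172	51202	G00012.1	1	+
chr1	51211	51241	G00012.1	1	+
chr1	51319	51349	G00012.1	1	+
chr1	51408	51438	G00012.1	1	+
chr1	51437	51467	G00012.1	1	+
chr1	51449	51479	G00012.1	1	+
chr1	51509	51539	G00012.1	1	+
chr1	51512	51542	G00012.1	1	+
chr1	51520	51550	G00012.1	1	+
chr1	51520	51550	G00012.1	1	+
chr1	51556	51586	G00012.1	1	+
chr1	51562	51592	G00012.1	1	+
chr1	51563	51593	G00012.1	1	+
chr1	51587	51617	G00012.1	1	+
chr1	51589	51619	G00012.1	1	+
chr1	51646	51676	G00012.1	1	+
chr1	51703	51733	G00012.1	1	+
chr1	51729	51759	G00012.1	1	+
chr1	51767	51797	G00012.1	1	+
chr1	51839	51869	G00012.1	1	+
chr1	51848	51878	G00012.1	1	+
chr1	51904	51934	G00012.1	1	+
chr1	51932	51962	G00012.1	1	+
chr1	51934	51964	G00012.1	1	+
chr1	51977	52007	G00012.1	1	+
chr1	52028	52058	G00012.1	1	+
chr1	52032	52062	G00012.1	1	+
chr1	52070	52100	G00012.1	1	+
chr1	52120	52150	G00012.1	1	+
chr1	52160	52190	G00012.1	1	+
chr1	52172	52202	G00012.1	1	+
chr1	52257	52287	G00012.1	1	+
chr1	52269	52299	G00012.1	1	+
chr1	52329	52359	G00012.1	1	+
chr1	52394	52424	G00012.1	1	+
chr1	52423	52453	G00012.1	1	+
chr1	52433	52463	G00012.1	1	+
chr1	52452	52482	G00012.1	1	+
chr1	52463	52493	G00012.1	1	+
chr1	52473	52503	G00012.1	1	+
chr1	68100	68130	G00016.1	1	+
chr1	90000	90030	G00021.1	1	-
chr1	94542	94572	G00022.1	1	+
chr1	108870	108900	G00025.1	1	-
chr1	118384	118414	G00027.1	1	-
chr1	131799	131829	G00029.1	1	-
chr1	132268	132298	G00029.1	1	-
chr1	132320	132350	G00029.1	1	-
chr1	145983	146013	G00032.1	1	+
chr1	146060	146090	G00032.1	1	+
chr1	191329	191359	G00042.1	1	+
chr1	199750	199780	G00043.1	1	-
chr1	204004	204034	G00044.1	1	+
chr1	216371	216401	G00047.1	1	-
chr1	216390	216420	G00047.1	1	-
chr1	217177	217207	G00047.1	1	-
chr1	219047	219077	G00047.1	1	-
chr1	219058	219088	G00047.1	1	-
chr1	220331	220361	G00047.1	1	-
chr1	220685	220715	G00047.1	1	-
chr1	220845	220875	G00047.1	1	-
chr1	224483	224513	G00048.1	1	+
chr1	230411	230441	Neurod6.1	1	+
chr1	232030	232060	Neurod6.1	1	+
chr1	241124	241154	Rbfox3.1	1	+
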