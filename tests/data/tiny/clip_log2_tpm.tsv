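transcript_id	Control_CLIP_1	Control_CLIP_2	Control_CLIP_3	Control_CLIP_4	Opto_CLIP_1	Opto_CLIP_2	Opto_CLIP_3	Opto_CLIP_4
G00000.1	9.397603976	8.572429876	8.72009653	9.622419072	8.378756438	6.493165227	7.610590695	6.782622612
G00001.1	9.882431187	9.042619805	8.535390158	8.773351701	9.527902613	8.231958312	9.01982006	9.306536363
G00002.1	9.493180498	9.915968178	9.725980821	9.989563072	9.737333356	8.809460457	9.609645361	9.25100131
G00003.1	9.514017954	9.433977074	10.09292512	9.950351809	8.933346327	9.75736204	9.508007986	9.648671873
G00004.1	12.60562118	11.9464667	12.30501045	11.87527426	12.52772885	11.62090776	11.69511074	11.74274392
G00005.1	12.51430317	11.50651292	11.6974101	11.07097802	14.8263993	15.23429752	14.94469838	14.96868061
G00006.1	13.62926375	13.49598903	13.45490672	13.92788063	11.63616886	12.12758942	11.72102881	11.3734544
G00007.1	12.1527511	12.12116876	12.60555955	12.26554961	12.56351914	12.28892933	11.79089284	11.76997977
G00008.1	9.482027087	9.296855128	10.77588442	10.03796538	9.80824034	10.15538852	9.916401155	9.840761134
G00009.1	11.26606996	11.29667963	10.92437438	10.43548081	14.3169548	14.25093077	13.61308158	13.53846113
G00010.1	9.17921472	10.94565642	10.17152402	10.7767036	9.848760759	9.485164383	9.468754805	8.381708557
G00011.1	7.143631278	7.776031978	8.703779967	9.215358567	8.639851004	8.517487196	8.255907923	7.799558078
G00012.1	15.52802327	15.25107266	16.07819782	15.12389534	18.60897869	19.5158763	19.3973622	18.74701826
G00013.1	8.738896173	9.217006474	9.661402613	7.978744463	7.709969423	8.32095003	8.331169062	8.741345361
G00014.1	5.670361938	5.828568562	6.139950912	5.909037372	5.480566021	5.342723902	5.407191243	4.710265465
G00015.1	13.06242924	12.42444111	12.35207388	12.09656892	12.42865975	12.2860861	11.62005771	11.92166944
G00016.1	11.64967516	12.50933174	10.95478394	11.8384299	11.85748421	11.62354955	12.15720922	12.90526075
G00017.1	12.09747731	11.16619743	12.00760161	12.64740277	11.86609771	11.97100268	11.54118707	11.944697
G00018.1	11.22213792	10.09785741	11.24424007	11.85680572	12.33694894	11.68240294	11.2797595	12.00026755
G00019.1	8.270788717	8.036713181	9.071564424	8.138015042	7.216228381	7.460712604	6.482978612	6.587827856
G00020.1	9.986322773	10.36912561	10.42116314	10.95401963	11.34047452	11.06216068	10.72747817	9.336981465
G00021.1	15.19039194	14.23010071	14.71208536	15.13900789	14.02784898	14.37791622	15.27347171	14.44033227
G00022.1	11.8325349	11.82421608	11.69936378	11.82583492	12.50232868	11.3723182	12.32196817	12.65071298
G00023.1	10.55827907	11.23342876	10.56596066	10.72235393	9.630641732	10.01698074	10.49609908	9.275856396
G00024.1	10.52753908	11.39348559	11.77468844	10.74000254	10.72568752	11.34847211	11.44388489	11.50726462
G00025.1	15.77813	15.58521819	15.17829061	15.00162237	14.7366047	14.93627884	14.4633966	14.5415123
G00026.1	7.199150747	7.830554601	6.638934644	7.548373981	7.271251433	8.095960879	7.375147508	7.018523451
G00027.1	12.92213033	12.49150228	12.62527472	12.76547969	12.26403302	12.18276661	12.16201244	11.43121474
G00028.1	13.13291562	13.18684422	11.89021856	12.75702873	8.445165626	8.707359407	8.386243802	9.288399531
G00029.1	14.59027305	15.66226569	16.16133446	15.35141439	16.02534553	14.12347348	14.91654358	15.16653589
G00030.1	9.403107923	8.456996154	8.089061575	8.309873239	8.254571058	8.479894112	8.350444636	8.809252241
G00031.1	12.26488971	11.53046877	11.10301558	11.59900037	11.60156863	12.33115411	11.18422832	11.85368121
G00032.1	13.46900817	13.0540119	13.57496904	12.86428342	13.37537137	12.77339885	13.87952877	13.574443
G00033.1	8.388346919	7.760736033	8.400549402	7.843780234	8.112201546	8.159958707	7.904914463	7.084819149
G00034.1	12.05893526	12.65237774	12.24320762	13.29090781	12.85289583	12.20758019	12.07384247	12.02317671
G00035.1	7.192959772	6.95644088	7.47748699	6.291776394	6.399986485	7.306842828	6.699196835	6.388492359
G00036.1	4.594079989	4.344158369	4.789474512	4.649071396	4.881047359	6.087550129	4.838431908	5.994411632
G00037.1	10.14573315	10.56174561	10.18839229	9.166725028	10.24919261	8.612295205	10.19277232	8.665123843
G00038.1	11.80652322	11.54035451	11.87302376	11.95407869	10.90678828	11.47228449	11.03503402	10.24348184
G00039.1	11.23405623	10.84582579	11.01771608	10.44092939	7.802471698	6.51607716	6.367299192	6.420602636
G00040.1	8.352918352	8.599221724	8.490449095	9.255366537	9.067451187	8.860613808	8.469001101	7.746865913
G00041.1	8.107189673	8.881667017	8.861602001	9.976675807	8.722518104	8.675885136	9.150370664	9.37179479
G00042.1	8.639543042	9.274578942	9.226303924	9.455826316	12.31394348	12.33976136	12.17750723	13.50607834
G00043.1	12.83562257	12.80284685	13.57655928	13.26230966	13.29643304	12.2833164	12.5997381	12.04291891
G00044.1	13.7835605	13.55268805	12.83805083	13.40159782	13.0827417	12.81817443	13.12186643	14.04304332
G00045.1	9.245888825	10.45204475	9.258466321	9.176685048	9.127243465	9.035461558	9.915336647	9.449667022
G00046.1	8.715900746	8.580345094	6.994356753	8.244804732	9.885966272	8.775039998	9.63522481	9.073401394
G00047.1	11.61782825	11.0025073	10.78580609	11.46084315	14.224345	13.89678752	15.31596027	13.33485118
G00048.1	12.80982107	12.53576264	12.8502934	12.41681557	12.20940162	12.96698676	13.26974502	11.79568981
G00049.1	13.54190471	14.34925065	14.26978365	13.34503637	11.80614816	13.14982707	12.47159034	13.45950612
Neurod6.1	13.46143981	13.8986439	14.12379897	14.68200993	14.71760841	13.55365496	13.81415906	14.87974237
Camk2a.1	11.3205178	10.41171069	10.79331779	10.51766506	11.47363213	10.08944283	11.39371157	10.6918071
Rbfox3.1	13.66982488	13.3611982	13.62762485	13.26231256	13.8981098	14.6066031	13.76307958	13.22433743
Snap25.1	11.3391142	11.12726859	10.89425863	11.63223026	11.41828944	11.76006021	11.21214252	11.2916591
Nrgn.1	11.89034887	11.97424722	11.99699096	11.18720979	11.64776367	12.02447597	11.47158502	12.61625395
Hpca.1	11.854658	12.39293826	11.81589371	12.93588145	12.08918598	11.67641353	11.84140857	12.69552805
Crym.1	8.147588543	8.207996134	8.14983608	7.523430849	8.168948126	7.672334818	8.035814374	7.843774075
Chn1.1	7.834994924	8.816746339	9.248980093	9.086290625	8.302269415	9.674070004	8.755494175	7.902991133
Gad2.1	8.098191932	8.801919332	7.980603521	7.797244667	7.042906131	8.10076452	8.393293447	8.392727216
Sst.1	9.744552993	9.883093749	9.50371035	9.1032962	8.113291128	8.789195539	9.787626932	8.897648508
Calb2.1	13.08151028	13.03326951	13.0079798	12.99504853	12.66967604	13.28153788	11.54141257	13.37619317
Pdgfra.1	5.566405117	6.181089856	5.186318471	5.971277221	4.996161432	6.186256909	6.583794571	6.289519928
Ptprz1.1	8.640640313	8.219547198	9.178708834	8.127314763	7.856026668	8.097536732	8.753183007	8.041008186
Mag.1	8.655394904	7.702317559	8.000440459	7.782412783	8.20478403	8.383106254	7.794686756	8.366920988
Mal.1	5.725696939	6.530516977	6.281675341	6.171221361	5.378361299	6.432997681	7.063259186	7.122781532
Mbp.1	8.134877551	8.512671709	7.989322702	9.414518406	8.277382719	8.135020634	8.596192991	8.548007767
Mobp.1	7.300902518	7.939788404	7.445850523	8.457426961	7.600291671	8.144345634	7.277352488	8.248813002
Plp1.1	8.936341262	9.884080601	9.474486962	9.097860977	9.388080459	8.762061848	8.361477621	9.422506337
Gfap.1	5.042711796	6.371721533	6.457463165	6.408049646	5.254193394	5.727872104	5.557692505	5.807546853
Glul.1	-8.260835121	-9.102329173	-8.805430639	-8.483687804	3.577574621	3.277762885	3.047871052	4.373143166
Aqp4.1	9.587576383	10.78454443	10.76179055	9.903591277	10.30822473	10.23473854	10.31173771	10.58824808
Aldh1l1.1	8.617711796	10.10431137	8.896466897	9.27030152	9.036319668	9.642052816	8.812666154	9.416564454
Pla2g7.1	7.239852159	6.486011527	6.909389884	6.601926949	7.657480825	6.285236502	6.696425012	7.404589879
Slc1a3.1	9.71738247	9.549422957	9.247468245	9.26212176	9.318788218	9.82132627	9.894333476	9.363101348
Aldoc.1	10.41512431	10.17132141	10.06577781	9.824827862	9.707306627	9.6332293	9.770788872	10.43033968
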