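chr1	21674	21704	G00004.1	1	+
chr1	26528	26558	G00006.1	1	+
chr1	28040	28070	G00006.1	1	+
chr1	30052	30082	G00007.1	1	-
chr1	38142	38172	G00009.1	1	-
chr1	48127	48157	G00012.1	1	+
chr1	48490	48520	G00012.1	1	+
chr1	48545	48575	G00012.1	1	+
chr1	48667	48697	G00012.1	1	+
chr1	48687	48717	G00012.1	1	+
chr1	48739	48769	G00012.1	1	+
chr1	48768	48798	G00012.1	1	+
chr1	48769	48799	G00012.1	1	+
chr1	48909	48939	G00012.1	1	+
chr1	49495	49525	G00012.1	1	+
chr1	49519	49549	G00012.1	1	+
chr1	49628	49658	G00012.1	1	+
chr1	49707	49737	G00012.1	1	+
chr1	49710	49740	G00012.1	1	+
chr1	49783	49813	G00012.1	1	+
chr1	49877	49907	G00012.1	1	+
chr1	49982	50012	G00012.1	1	+
chr1	50011	50041	G00012.1	1	+
chr1	50155	50185	G00012.1	1	+
chr1	50160	50190	G00012.1	1	+
chr1	50169	50199	G00012.1	1	+
chr1	50190	50220	G00012.1	1	+
chr1	50247	50277	G00012.1	1	+
chr1	50467	50497	G00012.1	1	+
chr1	50580	50610	G00012.1	1	+
chr1	50981	51011	G00012.1	1	+
chr1	51110	51140	G00012.1	1	+
chr1	51137	51167	G00012.1	1	+
chr1	51173	51203	G00012.1	1	+
chr1	51256	51286	G00012.1	1	+
chr1	51363	51393	G00012.1	1	+
chr1	51432	51462	G00012.1	1	+
chr1	51484	51514	G00012.1	1	+
chr1	51587	51617	G00012.1	1	+
chr1	51769	51799	G00012.1	1	+
chr1	51816	51846	G00012.1	1	+
chr1	51874	51904	G00012.1	1	+
chr1	51985	52015	G00012.1	1	+
chr1	52120	52150	G00012.1	1	+
chr1	52125	52155	G00012.1	1	+
chr1	52354	52384	G00012.1	1	+
chr1	52513	52543	G00012.1	1	+
chr1	63580	63610	G00015.1	1	-
chr1	70925	70955	G00016.1	1	+
chr1	75023	75053	G00017.1	1	-
chr1	75184	75214	G00017.1	1	-
chr1	80165	80195	G00018.1	1	+
chr1	90709	90739	G00021.1	1	-
chr1	90725	90755	G00021.1	1	-
chr1	92623	92653	G00022.1	1	+
chr1	95946	95976	G00022.1	1	+
chr1	102855	102885	G00024.1	1	+
chr1	104750	104780	G00024.1	1	+
chr1	108671	108701	G00025.1	1	-
chr1	108737	108767	G00025.1	1	-
chr1	108820	108850	G00025.1	1	-
chr1	118434	118464	G00027.1	1	-
chr1	120566	120596	G00027.1	1	-
chr1	120590	120620	G00027.1	1	-
chr1	121240	121270	G00027.1	1	-
chr1	125648	125678	G00028.1	1	+
chr1	126355	126385	G00028.1	1	+
chr1	128624	128654	G00028.1	1	+
chr1	130671	130701	G00029.1	1	-
chr1	130871	130901	G00029.1	1	-
chr1	130896	130926	G00029.1	1	-
chr1	130897	130927	G00029.1	1	-
chr1	131050	131080	G00029.1	1	-
chr1	131059	131089	G00029.1	1	-
chr1	131174	131204	G00029.1	1	-
chr1	131779	131809	G00029.1	1	-
chr1	132100	132130	G00029.1	1	-
chr1	132104	132134	G00029.1	1	-
chr1	132179	132209	G00029.1	1	-
chr1	132416	132446	G00029.1	1	-
chr1	132619	132649	G00029.1	1	-
chr1	132621	132651	G00029.1	1	-
chr1	132725	132755	G00029.1	1	-
chr1	132775	132805	G00029.1	1	-
chr1	132796	132826	G00029.1	1	-
chr1	132943	132973	G00029.1	1	-
chr1	132968	132998	G00029.1	1	-
chr1	133090	133120	G00029.1	1	-
chr1	133146	133176	G00029.1	1	-
chr1	133156	133186	G00029.1	1	-
chr1	133170	133200	G00029.1	1	-
chr1	133268	133298	G00029.1	1	-
chr1	133368	133398	G00029.1	1	-
chr1	139710	139740	G00031.1	1	-
chr1	144612	144642	G00032.1	1	+
chr1	145237	145267	G00032.1	1	+
chr1	146231	146261	G00032.1	1	+
chr1	146669	146699	G00032.1	1	+
chr1	146926	146956	G00032.1	1	+
chr1	152719	152749	G00034.1	1	+
chr1	167602	167632	G00037.1	1	-
chr1	175202	175232	G00038.1	1	+
chr1	196997	197027	G00043.1	1	-
chr1	197259	197289	G00043.1	1	-
chr1	198079	198109	G00043.1	1	-
chr1	198451	198481	G00043.1	1	-
chr1	198717	198747	G00043.1	1	-
chr1	198739	198769	G00043.1	1	-
chr1	198789	198819	G00043.1	1	-
chr1	199792	199822	G00043.1	1	-
chr1	201745	201775	G00044.1	1	+
chr1	203918	203948	G00044.1	1	+
chr1	219575	219605	G00047.1	1	-
chr1	223710	223740	G00048.1	1	+
chr1	224955	224985	G00048.1	1	+
chr1	226709	226739	G00049.1	1	-
chr1	226749	226779	G00049.1	1	-
chr1	228095	228125	G00049.1	1	-
chr1	228524	228554	G00049.1	1	-
chr1	230259	230289	Neurod6.1	1	+
chr1	230499	230529	Neurod6.1	1	+
chr1	231761	231791	Neurod6.1	1	+
chr1	232536	232566	Neurod6.1	1	+
chr1	232670	232700	Neurod6.1	1	+
chr1	232943	232973	Neurod6.1	1	+
chr1	233341	233371	Neurod6.1	1	+
chr1	236156	236186	Camk2a.1	1	-
chr1	239784	239814	Rbfox3.1	1	+
chr1	239971	240001	Rbfox3.1	1	+
chr1	240075	240105	Rbfox3.1	1	+
chr1	241049	241079	Rbfox3.1	1	+
chr1	242122	242152	Rbfox3.1	1	+
chr1	244523	244553	Snap25.1	1	-
chr1	250245	250275	Nrgn.1	1	+
chr1	253704	253734	Hpca.1	1	-
chr1	278767	278797	Calb2.1	1	+
chr1	279423	279453	Calb2.1	1	+
chr1	280494	280524	Calb2.1	1	+
chr1	281457	281487	Calb2.1	1	+
chr1	323716	323746	Aqp4.1	1	+
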