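transcript_id	gene_id	truth_class	beta	delta	ribo_log2fc	base_abundance	quadrant_truth
G00000.1	G00000	control_only	3	-3	1	8.330921031	fmrp_down_ribo_up
G00001.1	G00001	nontarget	0	0	0	11.14610829	unchanged
G00002.1	G00002	nontarget	0	0	0	11.54468246	unchanged
G00003.1	G00003	stringent_both	3	0	0	8.600830843	unchanged
G00004.1	G00004	nontarget	0	0	0	14.13598717	unchanged
G00005.1	G00005	opto_only	0	3	0	14.2138223	fmrp_up_ribo_unchanged
G00006.1	G00006	control_only	3	-3	1	12.73373481	fmrp_down_ribo_up
G00007.1	G00007	nontarget	0	0	0	13.89150385	unchanged
G00008.1	G00008	nontarget	0	0	0	11.88824077	unchanged
G00009.1	G00009	opto_only	0	3	0	13.44517833	fmrp_up_ribo_unchanged
G00010.1	G00010	nontarget	0	0	0	11.76439503	unchanged
G00011.1	G00011	nontarget	0	0	0	10.48516292	unchanged
G00012.1	G00012	opto_only	0	3	0	17.78873059	fmrp_up_ribo_unchanged
G00013.1	G00013	nontarget	0	0	0	10.5827927	unchanged
G00014.1	G00014	nontarget	0	0	0	7.951556293	unchanged
G00015.1	G00015	nontarget	0	0	0	14.12994526	unchanged
G00016.1	G00016	nontarget	0	0	0	14.40404764	unchanged
G00017.1	G00017	nontarget	0	0	0	13.90715102	unchanged
G00018.1	G00018	nontarget	0	0	0	13.43545494	unchanged
G00019.1	G00019	nontarget	0	0	0	9.928459698	unchanged
G00020.1	G00020	stringent_both	3	0	0	9.395266065	unchanged
G00021.1	G00021	stringent_both	3	0	0	13.81169879	unchanged
G00022.1	G00022	nontarget	0	0	0	13.66203009	unchanged
G00023.1	G00023	nontarget	0	0	0	12.14320758	unchanged
G00024.1	G00024	nontarget	0	0	0	13.0670244	unchanged
G00025.1	G00025	stringent_both	3	0	0	13.99649886	unchanged
G00026.1	G00026	nontarget	0	0	0	9.25347154	unchanged
G00027.1	G00027	nontarget	0	0	0	14.44087702	unchanged
G00028.1	G00028	control_only	3	-3	-1	11.7473083	fmrp_down_ribo_down
G00029.1	G00029	stringent_both	3	0	0	14.40906391	unchanged
G00030.1	G00030	nontarget	0	0	0	10.58691558	unchanged
G00031.1	G00031	nontarget	0	0	0	13.34700895	unchanged
G00032.1	G00032	nontarget	0	0	0	15.29322102	unchanged
G00033.1	G00033	nontarget	0	0	0	9.961976213	unchanged
G00034.1	G00034	nontarget	0	0	0	14.26738274	unchanged
G00035.1	G00035	nontarget	0	0	0	9.240002903	unchanged
G00036.1	G00036	nontarget	0	0	0	7.076530181	unchanged
G00037.1	G00037	nontarget	0	0	0	11.4604348	unchanged
G00038.1	G00038	nontarget	0	0	0	13.33271762	unchanged
G00039.1	G00039	control_only	3	-3	-1	10.10981864	fmrp_down_ribo_down
G00040.1	G00040	nontarget	0	0	0	10.70546376	unchanged
G00041.1	G00041	nontarget	0	0	0	10.77334273	unchanged
G00042.1	G00042	opto_only	0	3	0	11.49722521	fmrp_up_ribo_unchanged
G00043.1	G00043	nontarget	0	0	0	14.7147533	unchanged
G00044.1	G00044	nontarget	0	0	0	15.13011397	unchanged
G00045.1	G00045	nontarget	0	0	0	11.30473437	unchanged
G00046.1	G00046	nontarget	0	0	0	10.42108799	unchanged
G00047.1	G00047	opto_only	0	3	0	13.15382327	fmrp_up_ribo_unchanged
G00048.1	G00048	nontarget	0	0	0	14.72529509	unchanged
G00049.1	G00049	nontarget	0	0	0	15.26592961	unchanged
Neurod6.1	Neurod6	nontarget	0	0	0	14.17511034	unchanged
Camk2a.1	Camk2a	nontarget	0	0	0	10.7536549	unchanged
Rbfox3.1	Rbfox3	nontarget	0	0	0	13.82381899	unchanged
Snap25.1	Snap25	nontarget	0	0	0	11.32826544	unchanged
Nrgn.1	Nrgn	nontarget	0	0	0	11.63176154	unchanged
Hpca.1	Hpca	nontarget	0	0	0	11.99071371	unchanged
Crym.1	Crym	nontarget	0	0	0	8.028794856	unchanged
Chn1.1	Chn1	nontarget	0	0	0	8.799966362	unchanged
Gad2.1	Gad2	nontarget	0	0	0	12.01212581	unchanged
Sst.1	Sst	nontarget	0	0	0	13.09234677	unchanged
Calb2.1	Calb2	nontarget	0	0	0	17.05358639	unchanged
Pdgfra.1	Pdgfra	nontarget	0	0	0	9.875784002	unchanged
Ptprz1.1	Ptprz1	nontarget	0	0	0	11.93757812	unchanged
Mag.1	Mag	nontarget	0	0	0	12.02290341	unchanged
Mal.1	Mal	nontarget	0	0	0	10.42952763	unchanged
Mbp.1	Mbp	nontarget	0	0	0	12.39709801	unchanged
Mobp.1	Mobp	nontarget	0	0	0	12.12180417	unchanged
Plp1.1	Plp1	nontarget	0	0	0	12.65003583	unchanged
Gfap.1	Gfap	nontarget	0	0	0	9.852032928	unchanged
Glul.1	Glul	nontarget	0	0	0	6.429031795	unchanged
Aqp4.1	Aqp4	nontarget	0	0	0	14.24479822	unchanged
Aldh1l1.1	Aldh1l1	nontarget	0	0	0	13.13200642	unchanged
Pla2g7.1	Pla2g7	nontarget	0	0	0	10.91053467	unchanged
Slc1a3.1	Slc1a3	nontarget	0	0	0	13.43382324	unchanged
Aldoc.1	Aldoc	nontarget	0	0	0	13.85670053	unchanged
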