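# Published per-chromosome counts of mapped peptides and gene models from
# a large-scale wheat (IWGSC RefSeq v2.1) proteogenomics mapping study;
# used as a worked-example input for the chromosome summary machinery.
# exclude_from_stats marks the unplaced-scaffold bin, treated as an
# outlier by MIN/MAX/AVERAGE footers (SUM keeps every row).
chrom	hc_peptides	lc_peptides	novel_peptides	hc_mapped_genes	lc_mapped_genes	all_hc_genes	all_lc_genes	chrom_size_nt	exclude_from_stats
Chr1A	2883	235	79	1286	128	4359	6509	594442527	False
Chr1B	3957	296	154	1515	173	4736	8112	700547350	False
Chr1D	3332	224	67	1329	114	4487	6006	498638509	False
Chr2A	4599	322	204	1950	197	5840	7884	787782082	False
Chr2B	4523	448	207	1994	255	6152	9631	812755788	False
Chr2D	5739	332	137	2137	181	5885	7550	656544405	False
Chr3A	3095	231	87	1391	141	5237	7572	754128162	False
Chr3B	6971	849	467	2739	467	5941	9351	851934019	False
Chr3D	2589	207	63	1194	103	5306	6726	619618552	False
Chr4A	4113	327	130	1641	176	4870	7680	754227511	False
Chr4B	4048	318	83	1490	171	3878	6324	673810255	False
Chr4D	3848	277	274	1447	122	3582	4870	518332611	False
Chr5A	3464	225	64	1353	145	5450	7604	713360525	False
Chr5B	4752	443	117	1942	212	5574	8288	714805278	False
Chr5D	5327	372	105	1983	179	5574	6803	569951140	False
Chr6A	3631	287	152	1450	164	4141	6377	622669697	False
Chr6B	3423	283	106	1326	164	4627	8433	731188232	False
Chr6D	2802	196	76	1272	134	4012	5318	495380293	False
Chr7A	3052	236	124	1339	142	5573	8324	744491536	False
Chr7B	1991	212	101	956	138	4892	8602	764081788	False
Chr7D	4876	365	137	1866	190	5419	7666	642921167	False
ChrUn	64	21	0	12	6	1379	4216	351582993	True
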