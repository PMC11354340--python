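# Published per-tissue peptide counts from a large-scale wheat (IWGSC
# RefSeq v2.1) proteogenomics mapping study; used as a worked-example
# input for the tissue summary machinery.
tissue	tissue_nb	total_peptides	unique_sequences	hits
STORED GRAIN	1	123638	14768	5302
GRAIN DEVELOPMENT Z87	2	79826	25855	1915
GRAIN DEVELOPMENT Z83	3	84356	26818	1925
GRAIN DEVELOPMENT Z75	4	84112	28860	2298
GRAIN DEVELOPMENT Z71	5	122739	38790	3399
GRAIN DEVELOPMENT Z70	6	90963	27402	2579
ENDOSPERM	7	71182	22051	2389
EMBRYO	8	56489	25575	2154
PERICARP	9	102924	30070	3206
POLLEN	10	51251	14180	974
ANTHER	11	138308	36539	9743
LEMMA	12	119032	30885	2443
GLUME	13	131255	30545	3566
PALEA	14	92451	25637	3037
IMMATURE SPIKE	15	132013	39797	5547
RACHILLA	16	130559	35184	2346
SENESCING LEAF	17	61147	21388	1290
MATURE FLAG LEAF	18	78745	31959	1974
BOOTS	19	61154	29800	5167
NODE EXC	20	83310	35434	1384
NODE	21	73460	27589	2050
YOUNG FLAG LEAF	22	59966	25438	948
STEM	23	49383	21945	1687
COLEOPTILE	24	153644	45500	5839
MATURE ROOTS EXC	25	45620	34308	9357
MATURE ROOTS	26	89494	32528	2759
ROOT TIP	27	136241	39486	3140
ROOT VASCULATURE	28	66587	21877	1285
SEEDLING ROOT	29	135808	41551	3016
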