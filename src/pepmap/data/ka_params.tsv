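# Karlin-Altschul statistical parameters per (matrix, gap_open, gap_extend).
# gap_open = 0 and gap_extend = 0 denotes the ungapped fallback row for a matrix.
# Values are editable approximations in the range published for these scoring
# systems; e-values computed from them gate hit filtering only and are never
# compared against externally produced e-values.
matrix	gap_open	gap_extend	lambda	K
PAM30	0	0	0.3400	0.2830
PAM30	10	1	0.3090	0.1500
PAM30	9	1	0.2940	0.1100
PAM30	8	1	0.2700	0.0720
PAM30	5	2	0.2640	0.0790
PAM30	14	2	0.3090	0.1500
PAM30	15	3	0.3130	0.1600
PAM250	0	0	0.2290	0.0900
PAM250	21	1	0.2100	0.0600
BLOSUM45	0	0	0.2291	0.0924
BLOSUM45	19	1	0.2200	0.0800
BLOSUM90	0	0	0.3350	0.1900
BLOSUM90	11	1	0.3020	0.0930
BLOSUM90	9	1	0.2850	0.0750
BLOSUM90	6	2	0.2620	0.0620
BLOSUM90	9	2	0.2940	0.0850
BLOSUM90	8	2	0.2880	0.0780
BLOSUM62	0	0	0.3176	0.1340
BLOSUM62	11	1	0.2670	0.0410
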