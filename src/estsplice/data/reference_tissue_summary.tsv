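tissue	n_genes	n_introns	n_normal_introns	n_tumoral_introns	n_T_exons	n_N_exons
CNS	22	92	59	33	9	34
DER	4	16	5	11	8	1
EYE	2	7	3	4	2	1
KID	1	3	1	2	1	0
LIV	1	3	2	1	0	1
LYM	4	17	9	8	4	4
MSK	7	24	13	11	3	6
PLA	2	6	3	3	1	1
RES	2	12	5	7	4	2
TES	5	17	10	8	2	4
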