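chrom	n_markers	total_length_cM	avg_interval_cM	largest_gap_cM	gap_marker_left	gap_marker_right	gap_left_mb	gap_right_mb	gap_span_mb
1	69	202	3	29.9	SNP1-6	ac01000670	4.93	8.04	3.11
2	59	158.3	2.7	16.9	SNP2-29	aa02002928	22.56	25.59	3.03
3	40	157.3	4	28.8	aa03000857	SNP3-28	12.88	16.72	3.85
4	47	131.2	2.9	28.9	ac04000676	SNP4-46	16.74	20.06	3.32
5	29	132.5	4.7	36.6	ac05000011	aa05000263	0.46	3.89	3.43
6	51	121.4	2.4	14	ac06000665	AMP0074317	18.89	21.32	2.44
7	51	116.2	2.3	10	aa07001816	aa07001842	5.21	7.18	1.98
8	37	116.3	3.2	20	SNP8-28	aa08005473	10.55	19.45	8.9
9	23	85.8	3.9	18	AMP0066980	ac09000278	13.03	16.12	3.09
10	34	81.7	2.5	18	ac10000399	ac10000429	15.13	18.55	3.42
11	47	113	2.5	11.1	SNP11-34	aa11004155	18.74	20.35	1.61
12	40	99.3	2.5	8.5	aa12005168	SNP12-32	24.56	25.93	1.38
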