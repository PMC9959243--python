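chrom	n_markers	total_length_cM	avg_interval_cM	largest_gap_cM	gap_marker_left	gap_marker_right	gap_left_mb	gap_right_mb	gap_span_mb
1	45	195.6	4.4	30.2	aa01005142	ac01000670	4.84	8.04	3.2
2	29	163.2	5.8	18	aa02001544	aa02002928	22.53	25.59	3.06
3	26	159.8	6.4	30.7	aa03000857	ac03000493	12.88	17.36	4.48
4	23	132	6	31.1	ac04000676	aa04007763	16.74	20.53	3.79
5	19	130.2	7.2	34.9	ac05000011	aa05000263	0.46	3.89	3.43
6	23	116.7	5.3	16.8	ac06000103	ac06000385	6.09	8.66	2.57
7	24	115.5	5	23.7	aa07001934	aa07005205	19.24	23.71	4.47
8	16	112.8	7.5	23.7	aa08001560	aa08005473	8.84	19.45	10.62
9	15	83.6	6	24.7	ac09000231	ac09000278	11.75	16.12	4.36
10	14	80.5	6.2	17.9	ac10000399	ac10000429	15.13	18.55	3.42
11	29	112.7	4	13.7	aa11004053	aa11004155	18.05	20.35	2.3
12	29	94.8	3.4	11.2	aa12004649	aa12004709	17.48	19.86	2.38
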