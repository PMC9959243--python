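chrom	n_markers	total_length_cM	avg_interval_cM	largest_gap_cM	gap_marker_left	gap_marker_right	gap_left_mb	gap_right_mb	gap_span_mb
1	63	195.7	3.2	23	SNP1-18	ab01000593	6.77	9.42	2.65
2	50	160.1	3.3	25.7	aa02000707	SNP2-6	5.6	9.65	4.05
3	46	158	3.5	37.8	AMP0032478	AMP0019926	8.53	16.72	8.2
4	41	108.4	2.7	29.4	AMP0016137	aa04008763	23.02	31.41	8.38
5	27	143.3	5.5	36.9	ab05000017	AMP0033587	1.78	5.69	3.91
6	48	100.3	2.1	11.1	AMP0031636	SNP6-64	23.56	25.33	1.77
7	45	114.3	2.6	10.3	AMP0016664	aa07007162	24.67	26.64	1.97
8	35	111.5	3.3	25.7	aa08006250	SNP8-47	21.73	27.47	5.74
9	35	98.3	2.9	11.9	SNP9-26	SNP9-30	9.53	11.15	1.62
10	32	88.8	2.9	9.2	aa10000871	aa10000954	2.81	3.99	1.18
11	47	120.2	2.6	9.5	SNP11-25	aa11004155	18.74	20.35	1.61
12	32	86.3	2.8	15.4	aa12004743	AMP0028108	21.48	24.9	3.41
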