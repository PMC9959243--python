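chrom	n_markers	total_length_cM	avg_interval_cM	largest_gap_cM	gap_marker_left	gap_marker_right	gap_left_mb	gap_right_mb	gap_span_mb
1	39	168.4	4.4	25.4	aa01005142	ac01000670	4.84	8.04	3.2
2	36	132.7	3.8	16.8	aa02000715	aa02000772	6.1	9.6	3.49
3	27	137.2	5.3	30.7	aa03002463	ab03000579	29.09	32.98	3.89
4	24	143	6.2	49.1	ab04001157	aa04008763	23.13	31.41	8.28
5	15	88.6	6.3	38.8	aa05000007	ab05000128	0.03	12.4	12.37
6	22	116.8	5.6	19.3	ac06000764	aa06000938	21.7	25.52	3.82
7	25	105.4	4.4	17.9	aa07003357	aa07007162	22.25	26.64	4.39
8	24	95.7	4.2	18.2	aa08000774	aa08000792	2.23	5.08	2.85
9	10	72.3	8	23.3	ab09001035	aa09000103	16.58	21.63	5.05
10	18	75.9	4.5	11.2	aa10003172	ac10000429	17.12	18.55	1.43
11	30	103.7	3.6	14	aa11004053	aa11004155	18.05	20.35	2.3
12	16	65.5	4.4	11.9	aa12000100	aa12001794	2.84	5.53	2.69
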