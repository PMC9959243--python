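chrom	n_markers	total_length_cM	avg_interval_cM	largest_gap_cM	gap_marker_left	gap_marker_right	gap_left_mb	gap_right_mb	gap_span_mb
1	35	193.2	5.7	30.9	ac01000635	ab01000593	6.34	9.42	3.08
2	30	165.9	5.7	25.5	aa02000707	aa02000772	5.6	9.6	4
3	27	184.4	7.1	63.7	ab03000111	aa03002110	8.2	18.46	10.26
4	23	99.8	4.5	25.8	ab04001157	aa04008763	23.13	31.41	8.28
5	16	135.4	9	54.1	ab05000017	ab05000128	1.78	12.4	10.62
6	21	92.4	4.6	26.7	ac06000669	aa06001093	19.78	26.35	6.57
7	22	117.1	5.6	22.7	aa07005205	aa07007162	23.71	26.64	2.93
8	21	92.3	4.6	31.7	aa08000774	aa08000792	2.23	5.08	2.85
9	14	96.2	7.4	46.5	aa09000038	ac09000278	9.07	16.12	7.04
10	18	89	5.2	12.2	ac10000003	aa10000871	0.06	2.81	2.75
11	21	122.3	6.1	20.3	aa11004155	aa11005083	20.35	23.61	3.27
12	14	74.4	5.7	21.6	aa12000100	aa12004439	2.84	11.77	8.93
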