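chrom	n_markers	total_length_cM	avg_interval_cM	largest_gap_cM	gap_marker_left	gap_marker_right	gap_left_mb	gap_right_mb	gap_span_mb
1	32	204.1	6.6	41	aa01005142	aa01005640	4.84	10.97	6.13
2	24	135.9	5.9	16.8	ab02000190	aa02000772	6.52	9.6	3.08
3	31	160.4	5.3	43.4	ac03000229	ac03000493	9.29	17.36	8.07
4	17	99.4	6.2	35.3	aa04003679	ac04001045	7.79	21.53	13.73
5	18	122.3	7.2	20.1	ab05000280	aa05000868	22.81	26.84	4.03
6	21	128.8	6.4	38.5	ac06000665	aa06000938	18.89	25.52	6.63
7	28	106.9	4	19.4	aa07002141	aa07005154	20.25	23.24	2.99
8	24	106.9	4.6	17.3	aa08006250	ab08000934	21.73	24.84	3.11
9	13	80.2	6.7	33.5	ac09000238	ac09000278	12.73	16.12	3.39
10	15	115.9	8.3	47.2	aa10000749	aa10002652	2.15	11.97	9.82
11	27	109.9	4.2	16.4	aa11004053	aa11004155	18.05	20.35	2.3
12	27	94.6	3.6	10.6	aa12004649	aa12004670	17.48	19.14	1.65
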