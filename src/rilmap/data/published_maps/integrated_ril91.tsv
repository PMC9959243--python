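chrom	n_markers	total_length_cM	avg_interval_cM	largest_gap_cM	gap_marker_left	gap_marker_right	gap_left_mb	gap_right_mb	gap_span_mb
1	57	183.6	3.3	30.9	AMP0022274	ac01000670	4.97	8.04	3.06
2	51	138.8	2.8	16.4	aa02000715	aa02000772	6.1	9.6	3.49
3	41	150.5	3.8	35.8	SNP3-5	ab03000375	7.39	15.96	8.56
4	32	145.5	4.7	51.2	SNP4-39	ab04001335	23.27	31.52	8.25
5	25	107.2	4.5	33.7	SNP5-1	AMP0033375	0.02	5.69	5.68
6	39	117.6	3.1	14.5	SNP6-36	SNP6-39	23.66	25.23	1.57
7	32	113.7	3.7	17.9	aa07003357	SNP7-22	22.25	26.87	4.62
8	38	98.8	2.7	19.3	aa08006250	ab08000952	21.73	26.09	4.36
9	23	79.1	3.6	11.7	ab09001035	SNP9-13	16.58	19.61	3.03
10	28	76.8	2.8	9.7	aa10003142	SNP10-23	16.8	18.48	1.68
11	41	104.6	2.6	13.9	aa11004053	aa11004155	18.05	20.35	2.3
12	29	73.7	2.6	8.7	SNP12-42	SNP12-43	25.86	27.16	1.3
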