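chrom	n_markers	total_length_cM	avg_interval_cM	largest_gap_cM	gap_marker_left	gap_marker_right	gap_left_mb	gap_right_mb	gap_span_mb
1	48	200.4	4.3	36	AMP0078803	SNP01-16	4.99	10.73	5.74
2	48	141.3	3	16.9	ab02000190	aa02000772	6.52	9.6	3.08
3	41	156.5	3.9	27.8	SNP03-23	SNP03-24	12.5	16.72	4.22
4	32	117.8	3.8	27.5	SNP04-40	AMP0036911	13.99	18.61	4.63
5	29	114.2	4.1	17.8	ab05000280	aa05000868	22.81	26.84	4.03
6	38	128	3.5	22.4	ac06000665	AMP0001588	18.89	22.79	3.9
7	52	109.4	2.1	9	aa07007512	aa07007522	28.29	29.06	0.77
8	40	106.1	2.7	17.2	aa08006250	ab08000934	21.73	24.84	3.11
9	19	90.4	5	16.5	SNP09-4	ac09000278	14.82	16.12	1.29
10	25	106.9	4.5	23	AMP0074848	AMP0028902	3.56	6	2.44
11	39	113.6	3	15.1	aa11004053	aa11004155	18.05	20.35	2.3
12	44	104.5	2.4	12.5	AMP0021554	aa12000015	0	2.09	2.09
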