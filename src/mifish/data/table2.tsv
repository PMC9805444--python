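case	age	diagnosis	steatosis_pct	nas	tetra_octo_ratio	polyploid_fraction	ploidy_mean
1	41	NAFLD	10	3	9	3.90	2.09
2	32	NAFLD	20	3	20	2.90	2.08
3	69	NAFLD	5	1	16	6.70	2.15
4	36	NASH	40	4	18	3.80	2.08
5	27	NASH	70	4	9	2.90	2.07
6	64	NAFLD	20	3	5	10.00	2.26
7	54	NAFLD	20	2	12	1.90	2.03
8	29	NASH	70	5	26	1.80	2.03
9	45	NASH	60	5	7	4.40	2.11
10	57	NASH	80	5	3	2.00	2.06
11	54	NASH	30	5	9	3.50	2.08
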