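case	age	sex	tumor_size_cm	stage	grade	fibrosis	major_clone	minor_clone	clones_related	polyploid_clones	polyploid_detail	average_ploidy	instability_index	diversification	mutations
1	70	m	7	T2	G2	3	MYC+,MET+	MYC+,MET+,TP53-,HER2+	yes	yes	subset with equivalent aberrations	3.32	45.8	high	TERT_promoter;CTNNB1_S33P
2	69	m	10.4	T3	G3	2	TP53-,WWOX-	TP53-,WWOX-,HER2-,TERT-	yes	yes	exclusively, accumulated aberrations	4.05	26.17	high	TP53_H179R
3	73	m	14	T4	G3	3	WWOX-	TP53-	no	yes	<5%	2.38	36.4	high	TERT_promoter
4	71	m	13	T2	G3	2	HER2+,MYC+,TERT+	HER2+,MYC+,TP53-	yes	yes	<5%	2.58	33.66	high	CTNNB1_T41I;TERT_promoter
5	69	m	8	T3	G2	4	MYC+	MYC+,MET-	yes	yes	major clone 2, accumulated aberrations	2.47	16.7	low	TERT_promoter
6	77	m	2.9	T1	G1	1a	MYC+	MYC+	yes	yes	<5%	2.12	15.6	low	TERT_promoter
7	60	m	18	T1	G1	4	TERT+,MET+,WWOX-,TP53-	TERT+,MET+,WWOX-	yes	no		2.07	19.11	high	CTNNB1_S37A;TERT_promoter
8	77	m	9.5	T2	G3	3	HER2-,WWOX-	HER2-,WWOX-,TERT+	yes	no		2.12	27.7	high	TERT_promoter
9	64	f	9.2	T2	G3	1a	TP53-	TP53-,MYC-	yes	yes	subset with accumulated aberrations	3.17	24.08	high	TP53_R175H
10	63	m	4	T2	G2	4	TP53-	TP53-	yes	yes	major clone 2	2.23	6.55	low	TP53_S241T;TERT_promoter
11	54	m	7	T3	G2	4	CCND1+,TP53-	CCND1+,TP53-,MET+	yes	yes	<5%	2.05	14.2	low	TERT_promoter
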