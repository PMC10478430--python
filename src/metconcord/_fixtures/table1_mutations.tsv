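case_id	gene	hgvs_c	codon	exon	state	sift	polyphen	fathmm	primary	metastasis
1	APC	c.3871C>T	1291	15	Novel	N/A	N/A	N/A	+	+
1	APC	c.4468_4474delCATTTTG	1490-92	15	Novel	N/A	N/A	N/A	+	+
1	KRAS	c.35G>T	12	2	Known	Deleterious (0)	Probably damaging (0.984)	Pathogenic (0.98)	+	Wild
1	KRAS	c.183A>T	61	3	Known	Deleterious (0)	Possibly damaging (0.486)	Pathogenic (0.93)	+	+
1	TP53	c.518T>C	173	5	Known	Deleterious (0)	Probably damaging (0.996)	Pathogenic (0.99)	+	+
1	TP53	c.536A>G	179	5	Known	Deleterious (0)	Probably damaging (0.993)	Pathogenic (0.99)	+	Wild
1	SMAD4	c.1496G>A	499	9	Known	Deleterious (0)	Probably damaging (0.997)	Pathogenic (0.98)	+	+
2	APC	c.3707_3708delCA	1236	15	Known	N/A	N/A	N/A	+	+
2	APC	c.4033G>T	1345	15	Known	N/A	N/A	Pathogenic (0.85)	+	+
2	APC	c.4348C>T	1450	15	Known	N/A	N/A	Pathogenic (0.90)	+	+
2	KRAS	c.38G>A	13	2	Known	Deleterious (0.03)	Possibly damaging (0.517)	Pathogenic (0.98)	+	+
2	SMAD4	c.1478A>G	493	9	Known	Deleterious (0)	Probably damaging (0.96)	Pathogenic (1.0)	+	+
2	GNAS	c.2531G>A	844	8	Known	Deleterious (0)	Probably damaging (1)	Pathogenic (0.99)	+	Wild
3	APC	c.4012C>T	1338	15	Known	N/A	N/A	Pathogenic (0.90)	+	+
3	NRAS	c.181C>A	61	3	Known	Deleterious (0.01)	Possibly damaging (0.751)	Pathogenic (0.99)	Wild	+
3	TP53	c.797G>A	266	7	Known	Deleterious (0)	Probably damaging (0.998)	Pathogenic (1.0)	+	+
3	TP53	c.761T>A	254	7	Known	Deleterious (0)	Probably damaging (1)	Pathogenic (0.99)	Wild	+
4	KRAS	c.139G>C	47	2	Known	Deleterious (0)	Probably damaging (0.986)	N/A	+	+
4	TP53	c.517G>A	173	5	Known	Deleterious (0.03)	Probably damaging (0.954)	Pathogenic (0.99)	+	+
4	CDH1	c.1024A>T	342	8	Known	Deleterious (0.02)	Benign (0.089)	N/A	+	Wild
5	BRAF	c.1799T>A	600	15	Known	Deleterious (0)	Probably damaging (0.999)	Pathogenic (0.99)	+	+
5	TP53	c.723delC	241	7	Known	Tolerated (0.56)	Benign (0.033)	Neutral (0.36)	+	+
6	APC	c.3944C>A	1315	15	Known	Damaging due to Stop	N/A	Pathogenic (0.78)	+	+
6	TP53	c.54_55insAT	19	2	Novel	Deleterious (0)	Probably damaging (0.985)	Pathogenic (0.96)	+	+
7	.	.	.	.	.	.	.	.	.	.
8	.	.	.	.	.	.	.	.	.	.
9	APC	c.3949G>C	1317	15	Known	Tolerated (0.19)	Benign (0.002)	Pathogenic (0.98)	+	+
9	APC	c.4360delA	1454	15	Novel	N/A	N/A	N/A	+	+
9	KRAS	c.35G>C	12	2	Known	Deleterious (0.02)	Possibly damaging (0.739)	Pathogenic (0.98)	+	+
9	TP53	c.743G>A	248	7	Known	Deleterious (0)	Probably damaging (0.992)	Pathogenic (0.98)	+	+
10	APC	c.4059_4060insT	1376	15	Novel	N/A	N/A	N/A	+	+
10	TP53	c.845_846insCGGT	282	8	Novel	N/A	N/A	N/A	+	+
10	PIK3CA	c.1633G>A	545	9	Known	Deleterious (0.01)	Possibly damaging (0.868)	Pathogenic (0.97)	+	+
10	FBXW7	c.1168dupT	390	7	Novel	N/A	N/A	N/A	+	+
11	KRAS	c.38G>A	13	2	Known	Deleterious (0.03)	Possibly damaging (0.517)	Pathogenic (0.98)	+	+
11	TP53	c.821T>A	274	8	Known	Deleterious (0)	Probably damaging (0.994)	Pathogenic (1.0)	+	+
12	APC	c.4468_4474delCATTTTG	1490-92	15	Novel	N/A	N/A	N/A	+	+
12	KRAS	c.35G>T	12	2	Known	Deleterious (0)	Probably damaging (0.984)	Pathogenic (0.98)	+	+
12	TP53	c.536A>G	179	5	Known	Deleterious (0.01)	Probably damaging (0.971)	Pathogenic (0.99)	+	+
13	APC	c.3916G>T	1306	15	Known	N/A	N/A	Pathogenic (0.96)	+	+
13	TP53	c.524G>A	175	5	Known	Tolerated (0.13)	Benign (0.209)	Pathogenic (0.99)	+	+
14	APC	c.4660_4661insA	1554	15	Known	N/A	N/A	N/A	+	+
14	KRAS	c.35G>A	12	2	Known	Deleterious (0)	Benign (0.387)	Pathogenic (0.98)	+	+
14	TP53	c.745A>G	249	7	Known	Deleterious (0)	Probably damaging (0.994)	Neutral (0.41)	+	+
14	PIK3CA	c.1624G>A	542	9	Known	Tolerated (0.11)	Probably damaging (0.922)	Pathogenic (0.97)	+	+
15	APC	c.3957delT	1319	15	Known	N/A	N/A	N/A	+	+
15	KRAS	c.35G>A	12	2	Known	Deleterious (0)	Benign (0.387)	Pathogenic (0.98)	+	+
15	TP53	c.422G>A	141	5	Known	Deleterious (0)	Probably damaging (1)	Pathogenic (0.99)	+	+
16	NRAS	c.181C>A	61	3	Known	Deleterious (0.01)	Possibly damaging (0.751)	Pathogenic (0.99)	+	+
16	TP53	c.761T>A	254	7	Known	Deleterious (0)	Probably damaging (1)	Pathogenic (0.99)	+	+
17	APC	c.4455delT	1485	15	Known	N/A	N/A	N/A	+	+
17	KRAS	c.35G>C	12	2	Known	Deleterious (0.02)	Possibly damaging (0.739)	Pathogenic (0.98)	+	+
17	TP53	c.223_224dupCC	75	4	Novel	N/A	N/A	N/A	+	+
18	APC	c.4033G>T	1345	15	Known	N/A	N/A	Pathogenic (0.85)	+	+
18	TP53	c.524G>A	175	5	Known	Tolerated (0.13)	Benign (0.209)	Pathogenic (0.99)	+	+
19	APC	c.4479G>A	1306	15	Known	N/A	N/A	Neutral (0.46)	+	+
19	TP53	c.406delC	136	5	Known	N/A	N/A	N/A	+	+
20	TP53	c.638G>A	213	6	Known	Deleterious (0)	Probably damaging (0.992)	Pathogenic (0.99)	+	+
20	TP53	c.844C>T	282	8	Known	Deleterious (0)	Probably damaging (0.999)	Pathogenic (0.99)	+	+
21	APC	c.3980C>G	1327	15	Known	N/A	N/A	Pathogenic (0.90)	+	+
21	TP53	c.437G>A	146	5	Known	N/A	N/A	Neutral (0.17)	+	+
22	TP53	c.454_466delCCGCCCGGCACCC	152-156	5	Known	N/A	N/A	N/A	+	+
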