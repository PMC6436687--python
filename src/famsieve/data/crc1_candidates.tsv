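chrom	pos	ref	alt	type	gene	dbsnp_id	eur_aaf
chr3	77201736	G	A	intron	ROBO2	rs62251809	0.006
chr9	68504750	G	T	intergenic	-	rs201332223	-
chr10	17301230	A	G	intergenic	-	-	-
chr20	1813341	G	A	intergenic	-	rs180703964	0.002
chr20	1869125	C	T	intergenic	-	rs146934631	0.003
chr20	1872351	ACCT	A	upstream_gene	SIRPA	rs778710946	-
chr20	2111830	G	T	intron	STK35	rs35061411	0.001
chr20	2493371	T	G	upstream_gene	ZNF343	rs147087733	0.003
chr20	2690886	C	T	intron	EBF4	rs190090026	0.001
chr20	2733490	C	T	intron	EBF4	rs187805451	0.002
chr20	2738462	G	T	intron	EBF4	rs151095258	0.009
chr20	2790980	C	T	upstream_gene	C20orf141	rs952465216	-
chr20	2845312	ATGGGGCGTG	A	intron	PTPRA	rs748038717	0.008
chr20	3922982	AT	A	intron	RNF24	rs879326719	-
chr20	3998030	C	T	upstream_gene	RNF24	rs889095036	-
chr20	4222335	T	C	intron	ADRA1D	rs191072065	0
chr20	6815078	AAGAAAGAAAGAG	A	intergenic	-	rs144882419	-
chr20	7752380	C	A	intergenic	-	-	-
chr20	7887402	C	A	intron	HAO1	-	-
chr20	8067390	T	C	intergenic	-	-	-
chr20	8126125	G	A	intron	PLCB1	rs143541837	0.003
chr20	8228298	C	A	intron	PLCB1	rs534663667	0.003
chr20	8248534	T	G	intron	PLCB1	rs191574108	0.003
chr20	8302274	A	G	intron	PLCB1	rs182705116	0.002
chr20	8482637	T	C	intron	PLCB1	rs753952228	-
chr20	8541488	A	G	intron	PLCB1	-	-
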