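patient_id	sample_id	source	timepoint_years	chrom	pos	ref	alt	gene	protein_change	effect	vaf	alt_reads	depth	dbsnp	gnomad_af	clinvar	enigma	expected_category
P1	P1_WB_t0	WB	0.0	chr1	1001	A	G	TET2	A100T	synonymous	0.05	50	1000	False				filtered
P1	P1_WB_t0	WB	0.0	chr1	1002	A	G	TET2	A101T	nonsynonymous	0.009	9	1000	False				filtered
P1	P1_WB_t0	WB	0.0	chr1	1003	A	G	TET2	A102T	splice	0.01	10	1000	False				somatic
P1	P1_WB_t0	WB	0.0	chr1	1004	A	G	PPM1D	R552X	nonsynonymous	0.45	450	1000	False				somatic
P1	P1_WB_t0	WB	0.0	chr1	1005	A	G	PPM1D	R553X	nonsynonymous	0.451	451	1000	False				germline
P1	P1_WB_t0	WB	0.0	chr1	1006	A	G	ATM	Q200R	nonsynonymous	0.46	460	1000	True	0.2			germline
P1	P1_WB_t0	WB	0.0	chr1	1007	A	G	ATM	Q201R	nonsynonymous	0.40	400	1000	True				somatic
P1	P1_WB_t0	WB	0.0	chr1	1008	A	G	ATM	Q202R	nonsynonymous	0.401	401	1000	True				snp_excluded
P1	P1_WB_t0	WB	0.0	chr1	1009	A	G	ATM	Q203R	nonsynonymous	0.401	401	1000	False	0.011			snp_excluded
P1	P1_WB_t0	WB	0.0	chr1	1010	A	G	ATM	Q204R	nonsynonymous	0.401	401	1000	False	0.01			somatic
P1	P1_WB_t0	WB	0.0	chr1	1011	A	G	ATM	Q205R	nonsynonymous	0.401	401	1000	False	0.009			somatic
P1	P1_WB_t0	WB	0.0	chr2	2001	C	T	DNMT3A	R882H	nonsynonymous	0.42	420	1000	True				somatic
P1	P1_WB_t0	WB	0.0	chr2	2002	C	T	DNMT3A	R882C	nonsynonymous	0.42	420	1000	False	0.05			somatic
P1	P1_WB_t0	WB	0.0	chr2	2003	C	T	DNMT3A	R883H	nonsynonymous	0.42	420	1000	True				snp_excluded
P1	P1_WB_t0	WB	0.0	chr9	3001	G	T	JAK2	V617F	nonsynonymous	0.44	440	1000	False	0.02			somatic
P1	P1_WB_t0	WB	0.0	chr9	3002	G	T	JAK2	V617G	nonsynonymous	0.44	440	1000	True				snp_excluded
P1	P1_WB_t0	WB	0.0	chr2	4001	A	G	SF3B1	K700E	nonsynonymous	0.41	410	1000	True				somatic
P1	P1_WB_t0	WB	0.0	chr17	5001	C	G	SFRS2	P95H	nonsynonymous	0.41	410	1000	True				somatic
P1	P1_WB_t0	WB	0.0	chr21	6001	C	T	U2AF1	S34F	nonsynonymous	0.43	430	1000	False	0.03			somatic
P1	P1_WB_t0	WB	0.0	chr21	6002	C	T	U2AF1	Q157R	nonsynonymous	0.42	420	1000	True				somatic
P1	P1_WB_t0	WB	0.0	chr1	7001	A	G	GNB1	K57E	nonsynonymous	0.41	410	1000	True				somatic
P1	P1_WB_t0	WB	0.0	chr1	7002	A	C	GNB1	K57N	nonsynonymous	0.41	410	1000	True				snp_excluded
P1	P1_WB_t0	WB	0.0	chr2	2004	C	T	DNMT3A	R882H	nonsynonymous	0.009	9	1000	True				filtered
P1	P1_WB_t0	WB	0.0	chr9	3003	G	T	JAK2	V617F	nonsynonymous	0.46	460	1000	True				germline
P2	P2_WB_t0	WB	0.0	chr17	8001	G	A	PPM1D	W427X	nonsynonymous	0.010	20	2000	False				somatic
P3	P3_WB_t0	WB	0.0	chr17	8002	G	A	PPM1D	W428X	nonsynonymous	0.009	18	2000	False				somatic
P1	P1_WB_t0	WB	0.0	chr17	9001	C	A	BRCA1	E23X	stopgain	0.48	480	1000	False	0.0001	pathogenic		germline
P1	P1_WB_t0	WB	0.0	chr3	9501	A	G	KRAS	G12D	nonsynonymous	0.42	420	1000	False				somatic
P1	P1_WB_t0	WB	0.0	chr11	9601	T	A	CHEK2	T367fs	truncating_indel	0.02	20	1000	False				somatic
P1	P1_WB_t0	WB	0.0	chr5	9701	G	C	TERT	A100T	intronic	0.10	100	1000	False				filtered
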