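chromosome	gene	rsid	major_allele	minor_allele	maf	hwe_p
2	SPTBN1	rs11898505	G	A	0.37	0.75
6	RSPO3	rs7741021	A	C	0.39	0.84
6	CCDC170	rs4869739	A	T	0.35	0.22
6	ESR1	rs3020331	C	T	0.43	0.10
6	ESR1	rs2982552	C	T	0.49	0.19
6	ESR1	rs2234693	T	C	0.44	0.19
6	ESR1	rs9340799	A	G	0.34	0.75
7	WNT16	rs2908007	T	C	0.18	0.33
7	WNT16	rs2908004	T	C	0.22	0.25
7	WNT16	rs3801387	T	C	0.10	0.78
7	WNT16	rs3801385	A	G	0.09	0.33
7	WNT16	rs2707466	G	A	0.22	0.39
7	WNT16	rs2536184	G	A	0.03	0.09
8	OPG	rs4355801	A	G	0.39	0.17
8	OPG	rs3102735	T	C	0.12	0.35
8	OPG	rs2073618	G	C	0.46	0.63
10	DKK1	rs7902708	G	C	0.11	0.77
11	TMEM135	rs597319	A	G	0.31	0.19
11	LRP5	rs2306862	C	T	0.19	0.32
11	LRP5	rs556442	A	G	0.42	0.88
11	LRP5	rs3736228	C	T	0.17	0.46
13	RANKL	rs9594759	T	C	0.48	0.40
13	RANKL	rs12585014	G	A	0.18	0.11
13	RANKL	rs7988338	G	A	0.19	0.40
13	RANKL	rs2148073	C	G	0.18	0.60
17	SOST	rs4792909	G	T	0.42	0.31
17	SOST	rs851054	A	G	0.38	0.06
17	SOST	rs2023794	T	C	0.05	0.18
18	RANK	rs1805034	C	T	0.41	0.26
18	RANK	rs12458117	G	A	0.19	0.35
18	RANK	rs3018362	A	G	0.32	0.18
19	GPATCH1	rs10416265	A	G	0.32	0.06
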