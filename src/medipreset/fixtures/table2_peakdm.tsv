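gene_symbol	cpg_class	chrom	peakdm_baseline	peakdm_lp	peakdm_hp	printed_state	printed_reset_by	anomalous
Ddx3x	HCP	chrX	0.12	-0.29	-0.43	hyper	both	0
Ivd	ICP	chr3	0.21	-0.17	-0.54	hyper	both	0
Pcgf6	HCP	chr1	0.28	-0.28	-0.36	hyper	both	0
S100g	LCP	chrX	0.21	-0.44	-0.85	hyper	both	0
Xrcc2	HCP	chr4	0.27	-0.42	-0.46	hyper	both	0
Adora2b	HCP	chr10	0.34	-0.18		hyper	LP_only	0
Aplf	ICP	chr4	0.22	-0.38		hyper	LP_only	0
Ddx10	HCP	chr8	0.25	-0.31		hyper	LP_only	0
Gem	HCP	chr5	0.46	-0.10		hyper	LP_only	0
Hoxb7	ICP	chr10	0.38	-0.47		hyper	LP_only	0
Isca1	HCP	chr17	0.20	-0.28		hyper	LP_only	0
Mapk14	HCP	chr20	0.33	-0.16		hyper	LP_only	0
Nbn	HCP	chr5	0.27	-0.16		hyper	LP_only	0
Ndufa10	HCP	chr9	0.22	-0.21		hyper	LP_only	0
Ndufa10l1	HCP	chr9	0.22	-0.21		hyper	LP_only	0
Trpc5	LCP	chrX	0.47	-0.31		hyper	LP_only	0
Ar	LCP	chrX	0.22		-0.36	hyper	HP_only	0
Csf3	LCP	chr10	0.26		-0.36	hyper	HP_only	0
Atp1b1	HCP	chr13	-0.28	0.31	0.56	hypo	both	0
Ly6g6d	ICP	chr20	-0.28	0.15	0.28	hypo	both	0
Bax	HCP	chr1	-0.27	0.43		hypo	LP_only	0
Chrna4	HCP	chr3	-0.20	0.23		hypo	LP_only	0
Dll4	ICP	chr3	-0.33	0.36		hypo	LP_only	0
Lmna	ICP	chr2	-0.31	0.38		hypo	LP_only	0
Mafk	HCP	chr12	-0.24	0.26		hypo	LP_only	0
Neu1	ICP	chr20	-0.38	0.22		hypo	LP_only	0
Nfatc2	LCP	chr3	-0.39	0.47		hypo	LP_only	0
Plg	LCP	chr1	-0.31	0.26		hypo	LP_only	0
Vgf	HCP	chr12	-0.33	0.35		hypo	LP_only	0
Wnt5b	LCP	chr4	-0.28	0.16		hypo	LP_only	0
Casq2	LCP	chr2	-0.31		0.44	hypo	HP_only	0
Eif5a	HCP	chr10	-0.31		0.38	hypo	HP_only	0
Mapt	HCP	chr10	0.24		0.36	hypo	HP_only	1
Sp7	LCP	chr7	0.30		0.52	hypo	HP_only	1
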