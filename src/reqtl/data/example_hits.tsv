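trait	gene_id	chrom	tsnp_pos	reqtl_alleles	reqtl_pos	tsnp_id	reqtl_id	p_ase	p_gene	p_combined_published	q_published
Age	PCNT	21	47786817	G/T	47823229	21:47786817	21:47823229	4.29e-6	1.25e-1	8.28e-6	0.0735
Sex	BSG	19	582775	T/C	572878	19:582775	19:572878	1.75e-5	1.00e-1	2.50e-5	0.0567
Sex	NRAP	10	115412793	C/T	115385650	10:115412793	10:115385650	1.65e-7	5.61e-1	1.59e-6	0.0136
BMI	DAGLB	7	6449272	C/T	6476915	7:6449272	7:6476915	3.54e-2	1.55e-5	8.48e-6	0.0753
SBP	ELP2	18	33750046	T/G	33743660	18:33750046	18:33743660	3.24e-5	3.58e-2	1.70e-5	0.0607
SBP	FHOD3	18	34324091	T/C	33970347	18:34324091	18:33970347	2.82e-4	5.07e-3	2.06e-5	0.0607
SBP	IGF2R	6	160453978	T/C	160379096	6:160453978	6:160379096	1.34e-3	9.18e-4	1.80e-5	0.0607
TC_fasting	AGMAT	1	15909850	T/C	15918676	1:15909850	1:15918676	2.52e-3	8.60e-5	3.54e-6	0.0315
LDLc_fasting	AGMAT	1	15909850	T/C	15918676	1:15909850	1:15918676	1.20e-3	4.82e-4	8.88e-6	0.0501
LDLc_fasting	DEPTOR	8	121061879	G/T	120930135	8:121061879	8:120930135	4.43e-2	1.69e-5	1.13e-5	0.0501
LDLc_fasting	FHOD3	18	34232657	T/C	33970347	18:34232657	18:33970347	6.78e-3	4.54e-4	4.21e-5	0.0623
LDLc_fasting	TMEM261	9	7799653	A/G	7830189	9:7799653	9:7830189	8.31e-5	1.39e-2	1.69e-5	0.0501
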