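variant_id	effect_allele	other_allele	eaf	trait	measure	estimate	ci_lower	ci_upper	se	n_case	n_control	n_total	unit
rs11591147	T	G	1.5%	LDL-C	beta_continuous	-0.50	-0.54	-0.47	NA	NA	NA	77417	mmol_per_l
rs11591147	T	G	1.5%	CHD	log_odds	0.77	0.69	0.87	NA	37748	97202	NA	log_or
rs11591147	T	G	1.5%	IS	log_odds	1.04	0.84	1.28	NA	10307	19326	NA	log_or
rs505151	A	G	96.5%	LDL-C	beta_continuous	-0.09	-0.11	-0.07	NA	NA	NA	172970	mmol_per_l
rs505151	A	G	96.5%	CHD	log_odds	0.96	0.92	1.00	NA	60801	123504	NA	log_or
rs505151	A	G	96.5%	IS	log_odds	1.00	0.90	1.11	NA	10307	19326	NA	log_or
rs11206510	C	T	18.8%	LDL-C	beta_continuous	-0.08	-0.09	-0.07	NA	NA	NA	172970	mmol_per_l
rs11206510	C	T	18.8%	CHD	log_odds	0.93	0.90	0.95	NA	60801	123504	NA	log_or
rs11206510	C	T	18.8%	IS	log_odds	1.01	0.96	1.06	NA	10307	19326	NA	log_or
rs2479409	A	G	65.5%	LDL-C	beta_continuous	-0.06	-0.07	-0.06	NA	NA	NA	172970	mmol_per_l
rs2479409	A	G	65.5%	CHD	log_odds	0.97	0.95	0.99	NA	60801	123504	NA	log_or
rs2479409	A	G	65.5%	IS	log_odds	1.00	0.95	1.04	NA	10307	19326	NA	log_or
rs562556	G	A	18.3%	LDL-C	beta_continuous	-0.06	-0.08	-0.05	NA	NA	NA	172970	mmol_per_l
rs562556	G	A	18.3%	CHD	log_odds	1.00	0.98	1.03	NA	60801	123504	NA	log_or
rs562556	G	A	18.3%	IS	log_odds	1.06	1.01	1.11	NA	10307	19326	NA	log_or
rs11583680	T	C	14.1%	LDL-C	beta_continuous	-0.03	-0.05	-0.02	NA	NA	NA	172970	mmol_per_l
rs11583680	T	C	14.1%	CHD	log_odds	0.97	0.94	1.00	NA	60801	123504	NA	log_or
rs11583680	T	C	14.1%	IS	log_odds	1.00	0.94	1.06	NA	10307	19326	NA	log_or
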