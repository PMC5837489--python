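variant_id	effect_allele	other_allele	eaf	trait	measure	estimate	ci_lower	ci_upper	se	n_case	n_control	n_total	unit
rs11591147	T	G	1.5%	IS-cardioembolic	log_odds	1.31	0.87	1.95	NA	1859	19326	NA	log_or
rs11591147	T	G	1.5%	IS-large-artery	log_odds	1.10	0.73	1.64	NA	1817	19326	NA	log_or
rs11591147	T	G	1.5%	IS-small-vessel	log_odds	0.85	0.54	1.34	NA	1349	19326	NA	log_or
rs505151	A	G	96.5%	IS-cardioembolic	log_odds	0.96	0.78	1.16	NA	1859	19326	NA	log_or
rs505151	A	G	96.5%	IS-large-artery	log_odds	0.99	0.80	1.21	NA	1817	19326	NA	log_or
rs505151	A	G	96.5%	IS-small-vessel	log_odds	0.89	0.71	1.11	NA	1349	19326	NA	log_or
rs11206510	C	T	18.8%	IS-cardioembolic	log_odds	0.97	0.88	1.06	NA	1859	19326	NA	log_or
rs11206510	C	T	18.8%	IS-large-artery	log_odds	1.00	0.91	1.10	NA	1817	19326	NA	log_or
rs11206510	C	T	18.8%	IS-small-vessel	log_odds	0.95	0.85	1.05	NA	1349	19326	NA	log_or
rs2479409	A	G	65.5%	IS-cardioembolic	log_odds	1.00	0.92	1.09	NA	1859	19326	NA	log_or
rs2479409	A	G	65.5%	IS-large-artery	log_odds	0.98	0.90	1.07	NA	1817	19326	NA	log_or
rs2479409	A	G	65.5%	IS-small-vessel	log_odds	0.97	0.89	1.07	NA	1349	19326	NA	log_or
rs562556	G	A	18.3%	IS-cardioembolic	log_odds	1.06	0.96	1.17	NA	1859	19326	NA	log_or
rs562556	G	A	18.3%	IS-large-artery	log_odds	1.12	1.02	1.24	NA	1817	19326	NA	log_or
rs562556	G	A	18.3%	IS-small-vessel	log_odds	0.99	0.89	1.11	NA	1349	19326	NA	log_or
rs11583680	T	C	14.1%	IS-cardioembolic	log_odds	0.95	0.85	1.07	NA	1859	19326	NA	log_or
rs11583680	T	C	14.1%	IS-large-artery	log_odds	0.97	0.87	1.09	NA	1817	19326	NA	log_or
rs11583680	T	C	14.1%	IS-small-vessel	log_odds	0.94	0.83	1.07	NA	1349	19326	NA	log_or
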