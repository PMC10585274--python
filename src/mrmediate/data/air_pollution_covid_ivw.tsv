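exposure	outcome	n_snp	beta	lci	uci	pval
PM2.5	Susceptibility	249	0.040	-0.022	0.10	2.06E-01
NO2	Susceptibility	289	0.054	-0.0072	0.12	8.35E-02
NOx	Susceptibility	247	0.013	-0.052	0.079	6.92E-01
PM2.5	Hospitalization	247	0.10	-0.041	0.25	1.59E-01
NO2	Hospitalization	287	0.084	-0.052	0.22	2.24E-01
NOx	Hospitalization	247	0.039	-0.10	0.18	5.90E-01
PM2.5	Severity	247	0.044	-0.18	0.27	6.97E-01
NO2	Severity	288	0.15	-0.046	0.35	1.31E-01
NOx	Severity	247	0.12	-0.093	0.33	2.70E-01
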