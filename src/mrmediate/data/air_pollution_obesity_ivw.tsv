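exposure	outcome	n_snp	beta	lci	uci	pval
PM2.5	ASAT	240	0.12	0.023	0.21	1.49E-02
PM2.5	BMI	99	0.082	0.024	0.14	5.73E-03
PM2.5	HC	119	0.058	-0.043	0.16	2.63E-01
PM2.5	OB1	113	0.38	0.11	0.65	6.31E-03
PM2.5	OB2	113	0.37	-0.048	0.79	8.27E-02
PM2.5	OB3	113	0.54	-0.21	1.30	1.59E-01
PM2.5	VAT	240	0.093	0.0026	0.18	4.38E-02
PM2.5	WC	118	0.094	0.0099	0.18	2.85E-02
PM2.5	WHR	119	0.074	-0.010	0.16	8.44E-02
NO2	ASAT	283	0.013	-0.083	0.11	7.87E-01
NO2	BMI	110	0.013	-0.047	0.074	6.69E-01
NO2	HC	133	0.10	0.0057	0.19	3.77E-02
NO2	OB1	127	0.33	0.055	0.61	1.90E-02
NO2	OB2	127	0.35	-0.10	0.80	1.27E-01
NO2	OB3	123	0.59	-0.13	1.31	1.10E-01
NO2	VAT	283	-0.0042	-0.090	0.081	9.23E-01
NO2	WC	131	0.090	0.0092	0.17	2.90E-02
NO2	WHR	132	0.077	-0.0093	0.16	8.04E-02
NOx	ASAT	240	0.070	-0.034	0.17	1.87E-01
NOx	BMI	99	0.062	0.00044	0.12	4.84E-02
NOx	HC	119	0.16	0.060	0.26	1.74E-03
NOx	OB1	113	0.28	0.019	0.55	3.60E-02
NOx	OB2	113	0.66	0.24	1.07	1.85E-03
NOx	OB3	113	1.16	0.42	1.90	2.10E-03
NOx	VAT	240	0.048	-0.047	0.14	3.20E-01
NOx	WC	118	0.15	0.057	0.24	1.61E-03
NOx	WHR	119	0.13	0.036	0.22	6.37E-03
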