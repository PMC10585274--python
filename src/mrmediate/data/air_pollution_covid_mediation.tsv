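exposure	mediator	outcome	or	lci	uci	pval
PM2.5	BMI	Susceptibility	1.01	1.00	1.02	7.41E-03
PM2.5	OB1	Susceptibility	1.01	1.00	1.02	2.05E-02
PM2.5	WC	Susceptibility	1.01	1.00	1.02	4.10E-02
PM2.5	BMI	Hospitalization	1.03	1.01	1.06	6.82E-03
PM2.5	OB1	Hospitalization	1.04	1.01	1.08	1.49E-02
PM2.5	WC	Hospitalization	1.04	1.00	1.07	3.44E-02
PM2.5	BMI	Severity	1.05	1.01	1.09	6.82E-03
PM2.5	OB1	Severity	1.06	1.01	1.10	1.55E-02
PM2.5	WC	Severity	1.05	1.00	1.09	3.61E-02
NO2	OB1	Susceptibility	1.01	1.00	1.02	3.87E-02
NO2	WC	Susceptibility	1.01	1.00	1.02	4.16E-02
NO2	HC	Hospitalization	1.03	1.00	1.05	4.92E-02
NO2	OB1	Hospitalization	1.04	1.00	1.07	3.16E-02
NO2	WC	Hospitalization	1.04	1.00	1.07	3.49E-02
NO2	HC	Severity	1.04	1.00	1.08	4.95E-02
NO2	OB1	Severity	1.05	1.00	1.09	3.24E-02
NO2	WC	Severity	1.04	1.00	1.09	3.67E-02
NOx	HC	Susceptibility	1.02	1.00	1.03	7.29E-03
NOx	OB2	Susceptibility	1.02	1.00	1.03	1.62E-02
NOx	WC	Susceptibility	1.02	1.01	1.03	5.85E-03
NOx	WHR	Susceptibility	1.01	1.00	1.02	2.95E-02
NOx	HC	Hospitalization	1.04	1.01	1.07	5.35E-03
NOx	OB2	Hospitalization	1.05	1.02	1.09	5.41E-03
NOx	WC	Hospitalization	1.06	1.02	1.10	3.26E-03
NOx	WHR	Hospitalization	1.03	1.00	1.06	2.33E-02
NOx	HC	Severity	1.06	1.02	1.10	5.45E-03
NOx	OB2	Severity	1.07	1.02	1.12	7.30E-03
NOx	WC	Severity	1.07	1.02	1.13	3.86E-03
NOx	WHR	Severity	1.03	1.00	1.07	4.56E-02
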