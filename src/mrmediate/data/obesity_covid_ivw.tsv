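exposure	outcome	n_snp	beta	lci	uci	pval
ASAT	Susceptibility	146	0.036	0.0098	0.063	7.35E-03
BMI	Susceptibility	812	0.16	0.13	0.19	1.74E-27
HC	Susceptibility	174	0.096	0.060	0.13	1.95E-07
OB1	Susceptibility	88	0.035	0.020	0.051	1.20E-05
OB2	Susceptibility	75	0.024	0.011	0.036	1.51E-04
OB3	Susceptibility	37	0.0035	-0.0060	0.013	4.75E-01
VAT	Susceptibility	140	0.046	0.015	0.076	3.33E-03
WC	Susceptibility	160	0.12	0.079	0.16	1.44E-08
WHR	Susceptibility	130	0.093	0.043	0.14	3.03E-04
ASAT	Hospitalization	140	0.083	0.024	0.14	5.88E-03
BMI	Hospitalization	806	0.41	0.35	0.48	2.46E-40
HC	Hospitalization	174	0.26	0.18	0.35	1.09E-09
OB1	Hospitalization	88	0.11	0.069	0.15	7.97E-08
OB2	Hospitalization	74	0.078	0.053	0.10	5.77E-10
OB3	Hospitalization	37	0.014	-0.0073	0.036	1.95E-01
VAT	Hospitalization	134	0.11	0.056	0.17	1.23E-04
WC	Hospitalization	160	0.38	0.29	0.48	3.23E-16
WHR	Hospitalization	130	0.23	0.12	0.34	4.37E-05
ASAT	Severity	141	0.077	-0.0058	0.16	6.84E-02
BMI	Severity	811	0.59	0.50	0.67	1.44E-40
HC	Severity	174	0.36	0.25	0.48	1.64E-09
OB1	Severity	89	0.14	0.089	0.20	1.75E-07
OB2	Severity	75	0.10	0.065	0.14	1.20E-07
OB3	Severity	37	0.031	-0.0046	0.066	8.87E-02
VAT	Severity	134	0.11	0.015	0.20	2.24E-02
WC	Severity	160	0.48	0.35	0.61	5.99E-13
WHR	Severity	131	0.26	0.087	0.44	3.32E-03
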