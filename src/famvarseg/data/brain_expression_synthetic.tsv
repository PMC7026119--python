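gene	Amygdala	Anterior_cingulate_cortex	Caudate	Cerebellar_Hemisphere	Cerebellum	Cortex	Frontal_Cortex	Hippocampus	Hypothalamus	Nucleus_accumbens	Putamen	Substantia_nigra
ADGB	0.05	0.08	0.04	0.11	0.13	0.07	0.06	0.05	0.09	0.04	0.05	0.06
AOAH	3.10	2.45	1.80	1.20	1.35	2.90	2.75	2.10	2.60	1.95	1.70	2.30
CAND2	4.20	5.10	3.80	6.50	7.20	5.60	5.30	4.10	3.90	4.40	3.60	3.20
DCAF5	6.10	7.30	6.80	5.90	6.40	7.80	7.50	6.20	5.70	6.90	6.60	5.40
DIDO1	9.50	10.20	8.70	11.40	12.10	10.80	10.50	9.10	8.60	9.30	8.40	7.90
NCKAP5	1.40	1.90	1.10	0.80	0.95	2.20	2.05	1.60	1.30	1.20	1.00	0.90
PKHD1L1	0.02	0.03	0.01	0.02	0.04	0.03	0.02	0.02	0.05	0.01	0.02	0.03
RGS12	5.80	6.90	7.40	4.30	4.80	7.10	6.70	5.50	5.20	6.30	6.80	4.90
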