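gene	family	chrom	pos	protein_change	bd_carriers	bd_total	psy_carriers	psy_total	unaff_carriers	unaff_total	assoc_p_corrected	brain_expressed
ADGB	0014	6	147122366	p.R1529*	3	3	1	2	0	1	>0.99	no
ADGB	0085	6	147042628	p.W694C	3	3	0	0	0	1	>0.99	no
AOAH	0010	7	36661364	p.R202Q	4	4	0	0	4	6	>0.99	yes
AOAH	0012	7	36588239	p.I339T	3	3	0	0	0	1	>0.99	yes
CAND2	0045	3	12868994	p.A1089V	4	4	1	1	3	4	>0.99	yes
CAND2	0092	3	12856687	p.R352C	3	3	0	0	0	3	>0.99	yes
DCAF5	0009	14	69520635	p.R923Q	5	5	0	0	0	1	0.16	yes
DCAF5	1044	14	69520635	p.R923Q	5	6	1	1	1	3	>0.99	yes
DIDO1	0022	20	61511484	p.P1942S	4	4	0	2	4	5	>0.99	yes
DIDO1	0041	20	61525253	p.G956R	4	5	1	2	1	4	>0.99	yes
NCKAP5	0074	2	134275041	p.D19E	3	3	0	0	1	3	>0.99	yes
NCKAP5	0085	2	133539953	p.M1477I	3	3	0	0	0	1	>0.99	yes
PKHD1L1	0014	8	110534504	p.N4041Y	3	3	0	2	0	1	0.49	no
PKHD1L1	0109	8	110527435	p.R3864C	3	3	0	0	0	2	>0.99	no
RGS12	0045	4	3319538	p.Q547H	4	4	1	1	1	4	>0.99	yes
RGS12	0085	4	3318073	p.R59Q	3	3	0	0	0	1	>0.99	yes
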