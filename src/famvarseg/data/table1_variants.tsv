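gene	family	chrom	pos	ref	alt	protein_change	dbsnp	ref_maf	consequence	SIFT	P2_HDIV	P2_HVAR	LRT	MutationTaster
ADGB	0014	6	147122366	C	T	p.R1529*	NA	NA	nonsense	NA	NA	NA	NA	D
ADGB	0085	6	147042628	G	T	p.W694C	NA	NA	missense	D	D	D	N	D
AOAH	0010	7	36661364	C	T	p.R202Q	rs373491776	2.88E-04	missense	NA	D	D	D	D
AOAH	0012	7	36588239	A	G	p.I339T	rs144383001	3.64E-04	missense	D	D	D	N	D
CAND2	0045	3	12868994	C	T	p.A1089V	rs200074296	8.89E-05	missense	D	D	D	D	D
CAND2	0092	3	12856687	C	T	p.R352C	NA	3.38E-05	missense	D	D	D	D	D
DCAF5	0009	14	69520635	C	T	p.R923Q	rs751152443	1.11E-05	missense	D	D	D	D	D
DCAF5	1044	14	69520635	C	T	p.R923Q	rs751152443	1.11E-05	missense	D	D	D	D	D
DIDO1	0022	20	61511484	G	A	p.P1942S	NA	5.79E-05	missense	D	D	P	U	D
DIDO1	0041	20	61525253	C	T	p.G956R	rs143952489	9.20E-04	missense	D	D	P	N	N
NCKAP5	0074	2	134275041	G	C	p.D19E	NA	NA	missense	D	D	D	NA	N
NCKAP5	0085	2	133539953	C	T	p.M1477I	rs182514291	9.99E-04	missense	D	D	D	U	D
PKHD1L1	0014	8	110534504	A	T	p.N4041Y	NA	NA	missense	D	D	P	D	D
PKHD1L1	0109	8	110527435	C	T	p.R3864C	NA	3.70E-04	missense	D	D	D	D	D
RGS12	0045	4	3319538	G	T	p.Q547H	NA	NA	missense	D	D	P	D	N
RGS12	0085	4	3318073	G	A	p.R59Q	NA	2.21E-05	missense	D	D	P	N	N
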