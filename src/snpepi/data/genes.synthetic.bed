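27	949999	960000	GOSR2	coding
27	1000000	1010000	GJC1	coding
27	1100000	1120000	WNT3	coding
3	35400000	35450000	RGS7	coding
3	35800000	35850000	CHRM3	coding
3	34900000	34901000	MIR1784	noncoding
14	7200000	7230000	PDPK1	coding
14	7300000	7320000	IL21R	coding
18	10900000	10930000	GRB2	coding
18	10000000	10030000	SOCS3	coding
9	17000000	17050000	PIK3CA	coding
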