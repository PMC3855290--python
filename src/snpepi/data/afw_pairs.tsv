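GGA F	SNP1 name	GGA S	SNP2 name	Epistatic effect type	P-value	c (%)
0	GGaluGA194739	1	GGaluGA012915	AA	1.18×10^−11	1.08
1	Gga_rs13866305	3	Gga_rs13717259	AD	4.90×10^−12	0.68
1	Gga_rs13749637	13	Gga_rs16002106	AA	7.47×10^−12	1.40
1	Gga_rs15227054	13	Gga_rs16002106	AA	8.52×10^−12	1.38
1	Gga_rs13749637	13	GGaluGA097211	AA	1.02×10^−11	1.44
1	Gga_rs13749637	13	GGaluGA097233	AA	7.50×10^−13	1.54
1	Gga_rs15227054	13	GGaluGA097233	AA	8.57×10^−13	1.51
1	GGaluGA060937	14	GGaluGA101229	AA	3.17×10^−12	1.26
2	Gga_rs16026770	2	GGaluGA146662	AA	6.60×10^−12	1.05
2	Gga_rs14214495	13	Gga_rs15683090	AA	9.31×10^−12	1.14
3	Gga_rs14319575	3	Gga_rs14402423	AA	5.96×10^−12	0.91
3	Gga_rs14380677	3	Gga_rs16306728	AA	8.25×10^−12	1.10
3	Gga_rs16306728	3	GGaluGA231041	AA	1.09×10^−11	1.07
3	Gga_rs14319575	3	GGaluGA236122	AA	5.96×10^−12	0.91
3	Gga_rs14388313	5	Gga_rs14521876	AA	8.46×10^−13	1.14
3	Gga_rs14368109	10	GGaluGA071224	AD	6.80×10^−12	0.62
3	Gga_rs14368127	10	GGaluGA071224	AD	7.23×10^−12	0.63
3	Gga_rs16228738	14	Gga_rs14075705	AA	8.12×10^−13	1.42
3	Gga_rs16222762	20	Gga_rs14272866	AA	1.30×10^−12	1.13
3	Gga_rs16228738	23	Gga_rs13622160	AA	7.99×10^−12	1.20
3	Gga_rs16228738	23	GGaluGA188871	AA	9.80×10^−12	1.15
3	Gga_rs14340790	27	Gga_rs14303341	AA	1.16×10^−11	1.25
3	Gga_rs14341204	27	Gga_rs14303341	AA	1.42×10^−12	1.29
3	Gga_rs14341224	27	Gga_rs14303341	AA	6.31×10^−13	1.36
3	Gga_rs14341242	27	Gga_rs14303341	AA	5.68×10^−13	1.38
3	Gga_rs14341255	27	Gga_rs14303341	AA	5.68×10^−13	1.38
3	Gga_rs16254447	27	Gga_rs14303341	AA	6.31×10^−13	1.36
3	GGaluGA216762	27	Gga_rs14303341	AA	1.36×10^−12	1.31
4	Gga_rs15480969	20	Gga_rs14276105	AA	1.05×10^−11	1.54
7	GGaluGA317680	14	Gga_rs15718248	AA	1.05×10^−11	1.23
9	Gga_rs16674724	3	Gga_rs14319575	AA	1.05×10^−12	1.01
10	Gga_rs15583507	6	Gga_rs13561344	AA	2.80×10^−12	1.32
10	Gga_rs14009265	6	Gga_rs14560750	AA	5.35×10^−13	1.18
10	Gga_rs15583507	6	Gga_rs14560750	AA	2.15×10^−12	1.30
10	GGaluGA066690	10	GGaluGA066877	AA	4.66×10^−13	1.27
10	GGaluGA069801	23	Gga_rs13622160	AA	5.56×10^−12	1.15
10	GGaluGA069801	23	Gga_rs14290610	AA	4.64×10^−12	1.26
14	Gga_rs14068999	23	GGaluGA188871	AA	3.29×10^−12	1.12
14	Gga_rs15717370	23	GGaluGA188871	AA	3.29×10^−12	1.12
18	Gga_rs10729280	13	Gga_rs14988623	AD	6.56×10^−14	1.10
18	Gga_rs13569377	13	Gga_rs14988623	AD	2.54×10^−14	1.14
18	Gga_rs14416916	13	Gga_rs14988623	AD	9.00×10^−14	1.07
18	Gga_rs15469971	13	Gga_rs14988623	AD	2.92×10^−14	1.10
Z	Gga_rs14748835	8	Gga_rs14658668	AA	1.14×10^−11	1.20
Z	Gga_rs16094710	8	Gga_rs14658668	AA	1.14×10^−11	1.20
Z	Gga_rs16758057	8	Gga_rs14658668	AA	1.14×10^−11	1.20
Z	Gga_rs14748835	8	Gga_rs16650878	AA	1.11×10^−11	1.20
Z	Gga_rs16094710	8	Gga_rs16650878	AA	1.11×10^−11	1.20
Z	Gga_rs16758057	8	Gga_rs16650878	AA	1.11×10^−11	1.20
Z	Gga_rs14748835	8	GGaluGA333545	AA	1.14×10^−11	1.20
Z	Gga_rs16094710	8	GGaluGA333545	AA	1.14×10^−11	1.20
Z	Gga_rs15991936	10	Gga_rs15589655	AA	8.33×10^−12	1.28
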