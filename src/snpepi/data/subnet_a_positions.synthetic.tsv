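snp	chrom	pos
Gga_rs14303341	27	1111875
Gga_rs14340790	3	35026541
Gga_rs14341204	3	35548152
Gga_rs14341224	3	35582512
Gga_rs14341242	3	35616872
Gga_rs14341255	3	35651232
Gga_rs16254447	3	35685592
GGaluGA216762	3	35719953
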