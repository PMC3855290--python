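27	899999	1400000	QTL_11809
27	909999	1500000	QTL_11817
3	35299999	36000000	QTL_9418
1	0	1000000	QTL_3353
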