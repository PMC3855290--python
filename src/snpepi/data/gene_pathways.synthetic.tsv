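gene	pathway
GRB2	Insulin signaling pathway
PDPK1	Insulin signaling pathway
PIK3CA	Insulin signaling pathway
SOCS3	Insulin signaling pathway
GRB2	Jak-STAT signaling pathway
PIK3CA	Jak-STAT signaling pathway
SOCS3	Jak-STAT signaling pathway
IL21R	Jak-STAT signaling pathway
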