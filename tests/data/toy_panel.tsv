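gene	rvis_percentile	background_carrier_prob	chromosome
G1	2.0	0.05	chr1
G2	50.0	0.10	chr2
G3	100.0	0.08	chr3
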