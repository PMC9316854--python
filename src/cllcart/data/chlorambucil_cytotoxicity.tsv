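concentration_uM	concentration_mg_per_L	cytotoxicity_per_hour	cytotoxicity_per_day	fitted_cytotoxicity_per_day
0	0	0	0	0
1.5625	0.4753	0.0030	0.0720	0.0651
3.125	0.9507	0.0040	0.0960	0.0974
6.25	1.9013	0.0060	0.1440	0.1447
12.5	3.8026	0.0088	0.2112	0.2128
25	7.6053	0.0126	0.3024	0.3066
50	15.2106	0.0180	0.4320	0.4284
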