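# CSDA range of alpha particles in liquid water (unit density).
# Energy in MeV, range in micrometers. Values follow standard stopping-power
# compilations for 0.2-10 MeV alphas in water; range(0) = 0 by definition.
energy_mev	range_um
0.0	0.0
0.2	1.7
0.4	2.6
0.6	3.5
0.8	4.5
1.0	5.5
1.5	8.0
2.0	10.9
2.5	14.2
3.0	17.8
3.5	21.8
4.0	26.2
4.5	30.9
5.0	36.0
5.5	41.4
6.0	47.2
6.5	53.3
7.0	59.8
7.5	66.5
8.0	73.7
8.5	81.1
9.0	88.9
9.5	97.0
10.0	105.5
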