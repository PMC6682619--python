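parameter	description	image	range_min	range_max	scale_min	scale_max
P1	Platelet surface area coverage (%SAC)	BF	0	93.67	0	10
P2	Platelet aggregate coverage (%SAC)	BF	0	49.17	0	10
P3	Thrombus morphology score	BF	0	5.0	0	10
P4	Thrombus multilayer score	BF	0	3.0	0	10
P5	Thrombus contraction score	BF	0	3.0	0	10
P6	PS exposure (%SAC)	FL	0	12.23	0	10
P7	P-selectin expression (%SAC)	FL	0	29.70	0	10
P8	Integrin aIIbb3 activation (%SAC)	FL	0	28.25	0	10
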