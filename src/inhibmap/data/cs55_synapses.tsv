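label	target	area_um2	distance_um
S1	soma	0.116	0
S2	soma	0.221	0
S3	soma	0.052	0
S4	soma	0.120	0
S5	soma	0.436	0
S6	soma	0.194	0
S7	soma	0.344	0
S8	soma	0.151	0
S9	soma	0.068	0
S10	soma	0.138	0
S11	soma	0.132	0
S12	soma	0.211	0
S13	spine	0.092	0
D1	shaft	0.044	6
D2	shaft	0.176	8.6
Sp1	spine	0.180	12.6
D3	shaft	0.058	22.6
Sp2	spine	0.054	22.6
D4	shaft	0.060	24.7
Sp3	spine	0.099	24.9
Sp4	spine	0.067	24.9
D5	shaft	0.055	44.8
D6	shaft	0.060	84.5
D7	shaft	0.046	188.5
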