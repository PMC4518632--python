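label	target	area_um2	distance_um
S1	soma	0.350	0
S2	soma	0.174	0
S3	soma	0.194	0
S4	soma	0.232	0
D1	shaft	0.102	34
Sp1	spine	0.056	34
Sp2	spine	0.051	83
Sp3	spine	0.042	106
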