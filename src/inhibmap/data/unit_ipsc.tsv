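pair	charge_fC	area_um2
CS56	326.1	0.950
CS55	1057.8	3.011
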