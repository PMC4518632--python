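pair	stat	charge_fC	peak_pA
CS56	mean	193.1	-17.3
CS56	sd	56.2	3.0
CS56	max	326.1	-24.9
CS56	min	89.9	-11.8
CS56	n	60	60
CS56	average_trace	217.5	-14.2
CS55	mean	895.2	-91.3
CS55	sd	96.2	11.2
CS55	max	1057.8	-111.0
CS55	min	766.0	-74.0
CS55	n	10	10
CS55	average_trace	994.6	-89.4
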