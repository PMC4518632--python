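pair	basket_terminals	total_boutons
CS55	106	285
CS56	91	211
CS20	52	217
CS41	73	248
CS8	59	201
CS45	26	151
CS44	67	233
CS10	59	226
CS23	63	315
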