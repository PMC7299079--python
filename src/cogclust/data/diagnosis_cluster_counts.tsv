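method	diagnosis	low	high
twostep	BD	77	57
twostep	DD	41	52
twostep	PD	18	32
twostep	SZ	67	43
lca	BD	73	61
lca	DD	26	67
lca	PD	19	31
lca	SZ	66	44
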