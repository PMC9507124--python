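# name	affected	total
pooled_wild_type_blastula	113	117
pooled_wild_type_hatch	1111	1208
pooled_CI_blastula	45	159
pooled_CI_hatch	48	2397
pooled_rescue_blastula	57	66
pooled_rescue_hatch	1127	1281
pooled_reciprocal_blastula	47	47
pooled_reciprocal_hatch	1182	1299
live_wild_type_blastula	36	40
live_wild_type_hatch	53	58
live_CI_blastula	56	147
live_CI_hatch	18	110
wt_cycles_2_9	0	64
wt_cycles_10_11	0	13
wt_cycles_12_14	1	58
ci_cycles_2_9	2	63
ci_cycles_10_11	26	108
ci_cycles_12_14	72	190
rescue_cycles_12_14	7	128
egg_to_adult_wild_type	520	548
egg_to_adult_CI	94	137
egg_to_adult_rescue	511	588
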