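species	lost_with_repeat	lost_total	conserved_with_repeat	conserved_total
mouse	12	45	29076	148176
rat	12	86	28914	148176
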