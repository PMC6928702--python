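bout_id,start_s,end_s,n_steps,n_cycles,first_side
0,5.035000,44.320000,72,36,left
1,80.055000,109.490000,54,27,left
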