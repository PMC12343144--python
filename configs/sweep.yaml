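experiment: retrograde_sweep
params: bistable
rho0_levels: [0.005, 0.05, 0.1]
n_cycles: 10
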