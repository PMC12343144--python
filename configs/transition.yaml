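experiment: transition_map
params: bistable
rho0_levels: [0.005, 0.05, 0.1]
beta1_grid: {min: 1.0e-6, max: 1.0e-6, n: 1, scale: log}
omega_grid: {min: 2.0e-6, max: 3.0e-5, n: 25, scale: log}
vary: omega
range: [2.0e-6, 3.0e-5]
n_steps: 19
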