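experiment: dysfunction_heatmap
params: reference
rho0_levels: [0.05]
beta1_grid: {min: 1.0e-8, max: 1.0e-4, n: 15, scale: log}
omega_grid: {min: 1.0e-8, max: 1.0e-4, n: 15, scale: log}
n_cycles: 8
tau: 112.0
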