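# Small synthetic study region for the end-to-end demo pipeline:
# two disconnected 3x3 rook grids (an island borough analog),
# four years of monthly series, moderate per-area populations.
grid_rows: 3
grid_cols: 3
n_components: 2
T_months: 48
base_rate: 2.0e-3
population_range: [2000.0, 12000.0]
b0: 0.0
trend_slope: -0.4
amplitude_start: 12.0
amplitude_slope: -0.08
level: 120.0
phase: 0.5
noise_sd: 3.0
tau_u: 10.0
tau_v: 10.0
tau_gamma: 50.0
tau_phi: 50.0
tau_delta: 4.0
interaction_type: I
seed: 20
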