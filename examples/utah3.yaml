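# Stage-3 fibrotic atrium study at desk scale.
seed: 42
target_fb: 0.30
geometry:
  semi_axes_mm: [20.0, 17.0, 14.0]
  dx: 0.8
n_sites: 6
sim_duration_ms: 2500.0
dt_ms: 0.1
record_interval_ms: 2.0
calibrate: true
strategies: [1, 3, 4]
post_ablation_ms: 2000.0
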