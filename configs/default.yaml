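# Full study pipeline: simulate the default heterogeneous cohort, discover
# subgroups, and run the level x gap grid with both methods.
simulation:
  n_patients: 200
  t_min: 240
  t_max: 360
  n_channels: 6
  noise_sd: 1.75
  prevalence_target: 0.08
  gap_effect_lag: 1
  seed: 2026
  subgroup_effects:
    - {variable: age, hi: 50, coef: [0.55, -0.45, 0.5, 0.3, -0.25, 0.35], offset: -0.4}
    - {variable: age, lo: 50, coef: [-0.35, 0.5, 0.25, -0.55, 0.45, -0.3], offset: 0.4}
levels: [0, 1, 2, 4, 8]
gaps: [1, 5, 10, 20]
tree: {complexity: 1.0e-4, max_depth: 2, min_leaf: 20}
boosting: {n_estimators: 80, max_depth: 3, learning_rate: 0.15}
val_fraction: 0.3
seed: 2026
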