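# Miniature smoke-test pipeline (seconds, not minutes).
simulation:
  n_patients: 24
  t_min: 50
  t_max: 60
  n_channels: 3
  noise_sd: 1.0
  prevalence_target: 0.15
  gap_effect_lag: 1
  seed: 9
  subgroup_effects:
    - {variable: age, hi: 50, coef: [0.6, -0.4, 0.5], offset: -0.3}
    - {variable: age, lo: 50, coef: [-0.4, 0.5, 0.3], offset: 0.3}
levels: [0, 2]
gaps: [1, 5]
tree: {min_leaf: 5}
boosting: {n_estimators: 8, max_depth: 2, learning_rate: 0.3}
seed: 4
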