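# Desk-scale demo pipeline configuration (simulated discovery + validation
# cohorts; completes in well under a minute on one CPU).
simulation:
  n_case: 12
  n_control: 12
  n_met_features: 120
  n_prot_features: 80
  n_planted_met: 8
  n_planted_prot: 8
  effect_log2fc: 2.0
  noise_sd: 0.5
  missing_rate: 0.1
  n_pathways: 12
  pathway_size: 8
  n_planted_pathways: 2
n_folds: 5
n_permutations: 20
mccv_iterations: 20
n_val_case: 10
n_val_control: 8
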