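# Standard simulation conditions: five scenarios differing only in the
# population-average interaction coefficient b_bar (negative = competition,
# positive = cooperation).  All values merged over `defaults`.
defaults:
  mu_GR: 10.0
  var_A_GR: 1.0
  var_Ep_GR: 0.4
  var_Et_GR: 0.6
  var_AD: 0.000225
  var_AI: 0.000225
  var_ED: 0.000225
  var_EI: 0.000225
  start_weight_mean: 10.0
  start_weight_sd: 1.4142135623730951
  n_groups: 5000
  n_time_points: 10
  n_replicates: 100
  n_sires: 100
  n_dams_per_sire: 10
  n_offspring_per_dam: 10
  grouping: non-sib
scenarios:
  1: {b_bar: -0.08}   # strong competition
  2: {b_bar: -0.05}   # moderate competition
  3: {b_bar: 0.0}     # neutral
  4: {b_bar: 0.05}    # moderate cooperation
  5: {b_bar: 0.08}    # strong cooperation
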