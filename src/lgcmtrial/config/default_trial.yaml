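# Default synthetic-trial configuration: the study conditions the generator
# emulates.  Truth values mirror the magnitudes of the emulated trial's
# published tables (baseline depression ~8.2 with SD ~6, slope arm effect
# -0.319 implying a change-score SMD of -0.12, bell-count log2 baselines ~8.1).
# These are demo defaults, not assertions about any real dataset.
n_exp: 548
n_wait: 557
p_female: 0.748
age_mean: 23.68
age_sd: 10.44
months: [0.0, 1.0, 2.0, 3.0]
truth:
  qids:
    b00: 7.5
    b0exp: 0.0
    b0female: 0.9
    b10: -0.43
    b1exp: -0.319
    b1female: 0.0
    var_e0: 24.6
    var_e1: 1.0
    cov_e01: -1.0
    var_e2: 12.133
  lsas_v:
    b00: 28.0
    b0exp: 0.0
    b0female: 1.0
    b10: 0.7
    b1exp: 0.666
    b1female: 0.0
    var_e0: 300.0
    var_e1: 4.0
    cov_e01: 0.0
    var_e2: 60.0
  lsas_p:
    b00: 45.5
    b0exp: 0.0
    b0female: 1.0
    b10: -0.05
    b1exp: 0.319
    b1female: 0.0
    var_e0: 480.0
    var_e1: 4.0
    cov_e01: 0.0
    var_e2: 63.0
counts:
  bell:
    log2_mean_exp: [8.07, 7.93, 7.29, 6.65]
    log2_mean_wait: [8.15, 7.80, 6.99, 6.35]
    log2_sd: 2.6
    family: lognormal
    zipf_exponent: 2.0
  custom:
    log2_mean_exp: [7.71, 7.56, 6.50, 6.13]
    log2_mean_wait: [7.65, 7.48, 6.39, 5.90]
    log2_sd: 1.9
    family: lognormal
    zipf_exponent: 2.0
dropout: [0.0, 0.10, 0.15, 0.20]
mar_strength: 0.0
behavior_outcome_corr: 0.0
corr_behavior: bell
corr_outcome: qids
completion_p: 0.73
rewards:
  wave_payments: [500, 200, 200, 500]
  completion_bonus: 500
  n_bonus_months: 3
  waitlist_lottery_p: 0.73
seed: 0
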