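# Small end-to-end demonstration: simulate a 5-center cohort, fit the
# model ladder (1)-(4), calibrate the questionnaire exposure against the
# recall subsample and Rubin-combine bootstrap replicates.
seed: 20
simulate:
  n_centers: 5
  subjects_per_center: 150
  baseline_log_hazard: -4.0
  recall_subsample_fraction: 0.3
exposure: exposure_q
confounders: []
aggregate: []
levels: [1, 2, 3, 4]
centering: center_sex
calibration:
  enabled: true
  covariates: []
bootstrap_B: 2
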