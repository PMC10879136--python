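# CoMMpass-style calibration: n=752, 36-month landmark, single stratum.
# Genomic structure as in the BO calibration; the Weibull proportional-
# hazards model targets 3-year PFS 37/43/55% and OS 67/76/81% by class.
n_patients: 752
seed: 0
prevalence:
  Amp 1q: 0.365
  Del 13q: 0.44
or_1q_13q: 5.685
hd_given_class:
  1q&13+: 0.5525
  1q/13: 0.25
  1q&13-: 0.80
tihg_given_hd: 0.167
tihg_given_no_hd: 0.9035
tihg_partner_probs:
  t(11;14): 0.4416
  t(4;14): 0.4156
  t(14;16): 0.0983
  t(14;20): 0.0315
  t(6;14): 0.0130
odd_gain_probs:
  19: 0.390
  9: 0.383
  15: 0.371
  11: 0.323
  5: 0.321
  3: 0.309
  7: 0.244
  21: 0.191
odd_gain_rate_no_hd: 0.10
passenger_rates:
  1q&13+: 0.030
  1q/13: 0.009
  1q&13-: 0.012
passenger_weight_spread: 6.0
minor_rate: 0.02
clonality_mix: [0.70, 0.20, 0.10]
high_gain_frac_1q: 0.1863
high_gain_frac_other: 0.05
homo_loss_frac: 0.02
focal_frac: 0.10
weibull_shape: 1.2
pfs_scale_months: 55.270
os_scale_months: 131.791
log_hr_pfs:
  1q&13+: 0.50867
  1q/13: 0.34598
log_hr_os:
  1q&13+: 0.64233
  1q/13: 0.26419
censor_rate: 0.012
cohort_strata:
  CoMMpass: 1.0
landmark_months: 36
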