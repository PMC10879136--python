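# BO-style calibration: n=513 newly diagnosed patients, 60-month landmark.
# Prevalences target the printed cohort statistics (loss 13q 44%, HD 57.5%,
# t-IgH 48%, 1q&13+ ~26%, high-gain 1q 6.8% of all patients) and the Weibull
# proportional-hazards model targets 5-year PFS 22/37/47% and OS 50/74/78%
# for 1q&13+ / 1q/13 / 1q&13-.
n_patients: 513
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
pfs_scale_months: 75.830
os_scale_months: 191.463
log_hr_pfs:
  1q&13+: 0.69617
  1q/13: 0.27524
log_hr_os:
  1q&13+: 1.02596
  1q/13: 0.19218
censor_rate: 0.008
cohort_strata:
  BO-1: 0.7227
  BO-2: 0.1406
  BO-3: 0.1367
landmark_months: 60
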