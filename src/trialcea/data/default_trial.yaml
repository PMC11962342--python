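# Default simulation parameters: a 12-month two-arm treatment-resistant
# depression trial cohort in the Dutch care setting (rTMS + psychotherapy
# vs. next-step pharmacotherapy), 48 vs 41 patients.
#
# Utility / HDRS-17 moments, cost-category means and per-wave missingness
# rates reproduce the arm x wave summary statistics of such a trial.
# Correlation parameters (the utility-cost copula and within-patient
# loadings) and the missingness-model coefficients are NOT estimated from
# any dataset; they are plausible synthetic values, see docs/methods.md.

n_per_arm:
  intervention: 48
  control: 41

female_prob: 0.666
employment_prob: 0.404
wage_mean_per_hour: 20.0
wage_sd_per_hour: 7.0
min_wage_per_hour: 11.0
usual_hours_mean: 7.6
usual_hours_sd: 1.0

# arm -> [baseline, month 6, month 12]
utility_mean:
  intervention: [0.475, 0.630, 0.678]
  control: [0.463, 0.584, 0.515]
utility_sd:
  intervention: [0.265, 0.260, 0.267]
  control: [0.227, 0.290, 0.290]
hdrs_mean:
  intervention: [21.6, 12.2, 12.1]
  control: [21.2, 14.6, 13.4]
hdrs_sd:
  intervention: [4.1, 7.4, 8.3]
  control: [4.2, 6.3, 7.6]

# Recurring cost categories, euros per 4-week recall window.
# mean: overall mean (zero windows included); p_zero: probability of a
# zero window; cv: coefficient of variation of the positive part
# (gamma distributed).
healthcare_cost:
  intervention: {mean: [367.0, 301.0, 211.0], p_zero: [0.10, 0.15, 0.20], cv: [1.2, 1.4, 1.3]}
  control:      {mean: [315.0, 488.0, 379.0], p_zero: [0.10, 0.12, 0.15], cv: [1.1, 1.2, 1.3]}
family_help_cost:
  intervention: {mean: [93.0, 7.0, 119.0], p_zero: [0.75, 0.90, 0.80], cv: [2.0, 2.0, 2.0]}
  control:      {mean: [38.0, 49.0, 47.0], p_zero: [0.70, 0.75, 0.75], cv: [1.8, 1.8, 1.8]}
travel_cost:
  intervention: {mean: [15.0, 13.0, 9.0], p_zero: [0.20, 0.20, 0.30], cv: [1.0, 1.0, 1.0]}
  control:      {mean: [13.0, 18.0, 15.0], p_zero: [0.20, 0.20, 0.20], cv: [1.0, 1.0, 1.0]}

# Productivity losses in days per 4-week window.  Paid-work entries are
# means among EMPLOYED patients (unemployed patients have zero paid
# losses); unpaid-work entries are means over all patients.
paid_absenteeism_days:
  intervention: {mean: [4.6, 1.4, 1.3], p_zero: [0.55, 0.75, 0.80], cv: [1.2, 1.2, 1.2]}
  control:      {mean: [7.9, 5.4, 3.7], p_zero: [0.50, 0.60, 0.70], cv: [1.2, 1.2, 1.2]}
paid_presenteeism_days:
  intervention: {mean: [3.5, 3.1, 2.3], p_zero: [0.55, 0.60, 0.65], cv: [1.2, 1.2, 1.2]}
  control:      {mean: [6.7, 8.8, 2.7], p_zero: [0.50, 0.50, 0.60], cv: [1.2, 1.2, 1.2]}
unpaid_absenteeism_days:
  intervention: {mean: [0.04, 0.04, 0.20], p_zero: [0.95, 0.95, 0.90], cv: [1.5, 1.5, 1.5]}
  control:      {mean: [0.08, 0.02, 0.0], p_zero: [0.95, 0.97, 1.0], cv: [1.5, 1.5, 1.5]}
unpaid_presenteeism_days:
  intervention: {mean: [0.02, 0.11, 0.03], p_zero: [0.97, 0.92, 0.97], cv: [1.5, 1.5, 1.5]}
  control:      {mean: [0.19, 0.04, 0.0], p_zero: [0.92, 0.96, 1.0], cv: [1.5, 1.5, 1.5]}

# Intervention sessions between baseline and month 6 (administrative,
# never missing).  The control arm could receive the stimulation
# treatment during naturalistic follow-up.
rtms:
  intervention: {p_treated: 1.0, sessions: 25}
  control:      {p_treated: 0.58, sessions: 25}
psychotherapy_sessions_mean:
  intervention: 8.0
  control: 6.8

# Dependence structure (synthetic, not estimated): a Gaussian copula
# couples a per-patient utility latent, an HDRS latent and a cost-level
# latent; within-patient loadings give serial correlation across waves.
utility_within_corr: 0.6
hdrs_within_corr: 0.6
cost_within_corr: 0.5
hdrs_utility_corr: -0.6
utility_cost_corr: -0.3

# Wave-level (blockwise) missingness: logistic model on arm, gender,
# employment and baseline utility.  Baseline demographics and baseline
# HDRS are never masked; the wave-0 block covers utility and resource
# use only.
missingness:
  intercepts: {0: -3.85, 6: -1.2, 12: -0.97}
  arm_control: {0: 0.0, 6: 0.33, 12: 0.45}
  female: 0.1
  employed: -0.2
  baseline_utility: -0.4
  baseline_utility_center: 0.47

seed: 0
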