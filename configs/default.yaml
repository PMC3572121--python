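# Full default configuration for `emailnet report --config`.
# Exactly one of `synthetic` / `inputs` may be set.

synthetic:
  n_people: 1000
  response_rate: 0.47
  n_questions: 4
  max_names_per_question: 5
  naming_prob: 0.9
  target_tie_density: 0.004
  base_email_rate_per_week: 0.002
  tied_email_rate_per_week: 2.0
  volume_skew: 1.0
  asymmetry_beta_a: 2.0
  n_weeks: 22
  multi_recipient_fraction: 0.59
  trait_mean: 27.6
  rho_true: 0.4
  noise_sd: 4.5
  seed: 0

# inputs:
#   email_log: data/email_log.csv
#   survey: data/survey.csv
#   traits: data/traits.csv

output_dir: emailnet_out
single_grid_steps: 40   # 1 email/month .. 20 emails/week, log-spaced
rank_min: 2             # rank grid 2..25, step 1
rank_max: 25
logit_ridge: 0.0        # L2 fallback strength if the logit separates perfectly
window_weeks: null      # null = infer from the log span
make_plots: true
stability: true
stability_methods: [single_recipient, ranked_partner]
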