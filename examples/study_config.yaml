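# Annotated configuration for `trialcea simulate --config study_config.yaml`
# and as a reference for ScenarioConfig fields used by `trialcea run`.

generator:
  # arm sizes (intervention, control)
  n_per_arm: [165, 164]
  # baseline IDS-SR before truncation to the eligibility window [14, 38]
  baseline_ids_mean: 25.0
  baseline_ids_sd: 6.0
  # standardized 3-month treatment effect on the IDS-SR score
  treatment_effect_d: 0.41
  # mean score-point improvement in the control arm at 3 months
  mean_change_control: 2.0
  change_sd: 7.0
  # multiplier on the intervention arm's follow-up productivity day-count
  # means; 1.0 = arm-invariant follow-up costs, < 1.0 = cost-saving truth
  followup_productivity_treatment_factor: 1.0
  # per-arm mean baseline productivity cost targets, EUR per month
  productivity_baseline_means: [729.0, 582.0]
  employment_rate: 0.70

# Scenario options understood by `trialcea run` (one per invocation):
#   --scenario  main | paid_job_only | no_baseline_adjust |
#               healthcare_perspective | opportunity_costs |
#               regression_imputation | locf
#   --effect    responder_rate | qaly   (qaly needs --conversion-factor)
#   --b         bootstrap replicates per imputed dataset (default 5000)
#   --m         number of imputations for PMM (default 5)
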