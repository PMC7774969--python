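# Base-case parameter fixture, version 1.
#
# All values are the published base case of the Da Qing diabetes-prevention
# cost-effectiveness model: annual transition probabilities, hazard/relative
# risks, 2016 unit costs (Chinese yuan) and Chinese utility weights.
#
# Notes on structure:
#   * Age bands are data: lists of [age_low, age_high, value]; age_high null
#     means open-ended; band upper bounds are inclusive. The published bands
#     start at 45 but enrolment spans ages 25-74, so the youngest band is
#     extended down to age 0 (its value applies unchanged below 45).
#   * The published CVD-onset rows cover only ages 45-51 (0.009) and 76+
#     (0.0358); intermediate ages were not published. The gap 52-75 is filled
#     at load time by log-linear interpolation of the annual *rate*
#     (-ln(1-p)) between the two anchors (see `cvd_onset_interpolation`).
#   * The intervention effect on CVD onset (hazard ratio 0.74) applies from
#     age 52 upward; at 45-51 both arms share the same published probability.
#   * PSA distribution families follow standard cost-effectiveness practice:
#     beta for probabilities and utilities, gamma for costs, lognormal for
#     hazard/relative risks with sigma = (ln hi - ln lo)/3.92. Parameters
#     without a published interval (costs, utilities) use +/-20% of the
#     central value as the 95% interval; the one-time intervention cost is
#     fixed, as in the published probabilistic analysis.

version: 1

settings:
  horizon_mode: thirty_year      # thirty_year | lifetime
  cycle_length: 1                # years; the model is an annual-cycle chain
  discount_rate_costs: 0.03      # per year
  discount_rate_effects: 0.03    # per year
  wtp: 37446                     # yuan per QALY (63% of 2016 per-capita GDP)
  cohort_size: 10000
  seed: 12345
  half_cycle_correction: true
  max_age: 100                   # lifetime-horizon age cutoff

epi:
  p_npg_to_igt: 0.193
  p_igt_to_npg: 0.192
  # IGT -> DM2, control arm, by age band
  p_igt_to_dm2_by_band:
    - [0, 65, 0.1410]
    - [66, null, 0.1113]
  # intervention-vs-control hazard ratio on DM2 onset, by age band
  hr_dm2_by_band:
    - [0, 65, 0.57]
    - [66, null, 0.61]
  # DM2 -> CVD, control arm: published anchors; gap filled at load time
  p_dm2_to_cvd_anchors:
    - [0, 51, 0.009]
    - [76, null, 0.0358]
  cvd_onset_interpolation: loglinear_rate   # over ages 52-75
  hr_cvd_event: 0.74             # intervention vs control, ages >= 52
  hr_cvd_event_from_age: 52
  rr_dm2_mortality: 2.00         # vs general population, rate scale
  hr_dm2_mortality: 0.74         # intervention vs control
  rr_cvd_mortality: 2.13
  hr_cvd_mortality: 0.67
  hr_all_cause: 0.74             # published all-cause row; informational

costs:
  intervention_total: 3374       # yuan, whole 6-year program, per participant
  intervention_duration: 6       # years
  annual_screening: 422          # yuan per year, intervention arm
  dm2_treatment: 6436            # yuan per year in DM2
  cvd_treatment: 11680           # yuan per year, CVD on top of DM2
  amortize_intervention: true    # spread 3374 over the 6 years (else lump sum)
  screening_full_horizon: true   # screening every year alive (else 6 years)
  cvd_cost_includes_dm2: true    # CVD state accrues DM2 + CVD treatment

utilities:
  u_npg_at45: 0.936
  u_igt_at45: 0.931
  u_dm2_onset_at45: 0.925
  u_cvd_at45: 0.779
  dm2_decrement: 0.012           # informational: 0.936 - 0.012 ~ 0.925
  cvd_decrement: 0.158
  age_decrement_per_year: 0.003
  dm2_base_for_duration_rule: 0.832   # published worked-example base utility
  npg_multiplier: 1.0            # optional "99.08% of NPG" adjustment; off

lifetable_source: synthetic      # or a CSV path with columns age,qx

psa_specs:
  - {parameter_name: p_npg_to_igt,      family: beta,      central: 0.193, ci_low: 0.175, ci_high: 0.275}
  - {parameter_name: p_igt_to_npg,      family: beta,      central: 0.192, ci_low: 0.185, ci_high: 0.200}
  - {parameter_name: p_cvd_onset_45_51, family: beta,      central: 0.009, ci_low: 0.002, ci_high: 0.016}
  - {parameter_name: hr_dm2_onset_45_65, family: lognormal, central: 0.57, ci_low: 0.41, ci_high: 0.81}
  - {parameter_name: hr_dm2_onset_66,   family: lognormal, central: 0.61,  ci_low: 0.45,  ci_high: 0.83}
  - {parameter_name: hr_cvd_event,      family: lognormal, central: 0.74,  ci_low: 0.59,  ci_high: 0.92}
  - {parameter_name: rr_dm2_mortality,  family: lognormal, central: 2.00,  ci_low: 1.93,  ci_high: 2.08}
  - {parameter_name: hr_dm2_mortality,  family: lognormal, central: 0.74,  ci_low: 0.61,  ci_high: 0.89}
  - {parameter_name: rr_cvd_mortality,  family: lognormal, central: 2.13,  ci_low: 2.01,  ci_high: 2.26}
  - {parameter_name: hr_cvd_mortality,  family: lognormal, central: 0.67,  ci_low: 0.48,  ci_high: 0.94}
  - {parameter_name: intervention_total, family: fixed,    central: 3374,  ci_low: null,  ci_high: null}
  - {parameter_name: annual_screening,  family: gamma,     central: 422,   ci_low: 337.6, ci_high: 506.4}
  - {parameter_name: dm2_treatment,     family: gamma,     central: 6436,  ci_low: 5148.8, ci_high: 7723.2}
  - {parameter_name: cvd_treatment,     family: gamma,     central: 11680, ci_low: 9344.0, ci_high: 14016.0}
  - {parameter_name: u_npg_at45,        family: beta,      central: 0.936, ci_low: 0.7488, ci_high: 0.99}
  - {parameter_name: u_igt_at45,        family: beta,      central: 0.931, ci_low: 0.7448, ci_high: 0.99}
  - {parameter_name: u_dm2_onset_at45,  family: beta,      central: 0.925, ci_low: 0.7400, ci_high: 0.99}
  - {parameter_name: u_cvd_at45,        family: beta,      central: 0.779, ci_low: 0.6232, ci_high: 0.9348}
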