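# Default configuration: a pre/post pediatric sepsis triage program at a
# Ugandan regional referral hospital, 2021 USD.
#
# Trial counts are reconstructed from published phase-level rates
# (events = round(rate x n)); unit costs are a SYNTHETIC schedule -- the
# underlying facility-survey unit costs are not public -- calibrated to
# published Ugandan pediatric pneumonia cost ranges (government episode
# cost of roughly $7-12 per admitted child; out-of-pocket fees near $15).

trial:
  pre:
    n: 1402
    admitted: 313
    inhospital_deaths: 9
    deaths_7day: 3
    readmissions: 34
    care_no_admit: 77
    timely_bundle: 10
    lost_to_followup: 25
    n_months: 9            # April-December
    los_mean: 4.0
    los_ci: [3.8, 4.5]
    readmit_los_mean: 4.0
    readmit_los_ci: [2.8, 4.8]
    age_mean: 2.0
    age_sd: 2.5
  post:
    n: 1942
    admitted: 270
    inhospital_deaths: 3
    deaths_7day: 2
    readmissions: 23
    care_no_admit: 76
    timely_bundle: 14
    lost_to_followup: 27
    n_months: 9
    los_mean: 4.0
    los_ci: [3.9, 4.4]
    readmit_los_mean: 4.0
    readmit_los_ci: [3.1, 5.1]
    age_mean: 2.0
    age_sd: 2.0

# Caregiver workdays missed, by resource-use stratum (mean and 95% CI).
missed_days:
  admit_none:      {mean: 4.0,  ci: [4.0, 5.0]}
  nonadmit_none:   {mean: 2.0,  ci: [2.0, 2.0]}
  admit_readmit:   {mean: 12.0, ci: [5.0, 18.0]}
  nonadmit_readmit: {mean: 6.0, ci: [5.0, 7.0]}
  admit_care:      {mean: 6.0,  ci: [3.0, 8.0]}
  nonadmit_care:   {mean: 4.0,  ci: [3.0, 4.0]}

unit_costs:
  currency_year: 2021
  source_label: "synthetic schedule calibrated to published Ugandan pediatric cost ranges"
  government:
    outpatient_visit: {mean: 1.20, ci: [0.84, 1.56]}
    inpatient_day:    {mean: 2.00, ci: [1.40, 2.60]}
  patient:
    outpatient_visit: {mean: 2.30, ci: [1.61, 2.99]}
    inpatient_day:    {mean: 3.60, ci: [2.52, 4.68]}

economics:
  discount_rate: 0.03
  program_horizon_years: 5
  annual_children: 28000
  # Average daily wage (USD/day); the published average monthly wage of
  # about $57 is the cross-check (57 * 12 / 365 workday-adjusted).
  daily_wage: {mean: 3.075, ci: [2.46, 3.69]}
  life_expectancy: 62.85   # Uganda, years at birth, 2021 vintage
  mean_age_at_death: {mean: 2.0, ci: [0.7, 3.0]}
  bundle_mortality_or: 0.64   # literature OR, timely sepsis bundle vs not
  wtp_hoc: 174.12
  wtp_gdp: 883.89
  ugx_per_usd: 3587.075
  deflator: {2018: 90.1, 2021: 100.0}   # Uganda GDP deflator index
  program_cost_items:
    - {label: "infrastructure: dashboard, tablets, mounting", amount: 4200.00, currency: USD, year: 2021}
    - {label: "shared consumables: reusable RFID tracking bands", amount: 1200.00, currency: USD, year: 2021}
    - {label: "one-time technologist set-up fee", amount: 3132859.83, currency: UGX, year: 2021}

psa:
  n_draws: 10000
  lambda_max: 1000.0
  lambda_step: 1.0

scenarios:
  - {name: base, annuitization_rate: 0.03}
  - {name: annuitization_0pct, annuitization_rate: 0.0}
  - {name: annuitization_1pct, annuitization_rate: 0.01}
  - {name: annuitization_5pct, annuitization_rate: 0.05}
  - {name: no_sustainability, sustain_beyond_study: false}
  - {name: low_volume_months_excluded, month_exclusion: true, month_threshold: 0.5}
  - {name: admission_penalty_25, admission_penalty: 0.25}
  - {name: admission_penalty_50, admission_penalty: 0.50}
  - {name: admission_penalty_75, admission_penalty: 0.75}
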