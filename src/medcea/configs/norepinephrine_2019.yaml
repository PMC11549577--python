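# Continuous-infusion norepinephrine, in-hospital trial evidence, 2019 USD.
# SYNTHETIC RECONSTRUCTION: per-arm overdose/underdose counts and timing
# summaries for this drug were not published; the counts below are chosen so
# the pooled-denominator preventable-errors-per-administration equals the
# published 0.484. Cost and ADE blocks are the shared published parameters.
drug: norepinephrine
route: continuous_infusion
currency_year: 2019
exchange_rate:
  value: 1.03
  units: USD per CHF
trial:
  control:
    n_administrations: 62
    overdoses:
      value: 6.0
      source: reconstructed to match published 0.484 errors prevented per administration
      distribution: {kind: uniform}
    underdoses:
      value: 26.0
      source: reconstructed to match published 0.484 errors prevented per administration
      distribution: {kind: uniform}
    prep_time_mean_s:
      value: 240.0
      units: seconds
      source: reconstructed (plausible continuous-infusion preparation time)
      distribution: {kind: normal, sd: 80.0, lower_bound: 0.0}
    prep_time_sd_s: 80.0
  app:
    n_administrations: 62
    overdoses:
      value: 1.0
      source: reconstructed
      distribution: {kind: uniform}
    underdoses:
      value: 1.0
      source: reconstructed
      distribution: {kind: uniform}
    prep_time_mean_s:
      value: 210.0
      units: seconds
      source: reconstructed
      distribution: {kind: normal, sd: 70.0, lower_bound: 0.0}
    prep_time_sd_s: 70.0
ade:
  p_ade:
    value: 0.111
    distribution: {kind: normal, sd: 0.011, lower_bound: 0.0, upper_bound: 1.0, ci_low: 0.091, ci_high: 0.135}
  p_cat_f:
    value: 0.03
    distribution: {kind: normal, sd: 0.0189, lower_bound: 0.0, upper_bound: 1.0, ci_low: 0.006, ci_high: 0.08}
  clos_days:
    value: 0.64
    units: days
    distribution: {kind: normal, sd: 0.1, lower_bound: 0.0, ci_low: 0.4, ci_high: 0.9}
  daily_cost:
    value: 229.7
    units: USD/day
    distribution: {kind: uniform, low: 183.8, high: 275.7}
  excess_complication_cost:
    value: 22080.0
    units: USD
    distribution: {kind: uniform, low: 17664.0, high: 26496.0}
  excess_fraction: 0.9184
costs:
  development_cost:
    value: 186026.0
  maintenance_annual:
    value: 37205.3
    distribution: {kind: uniform, low: 29764.2, high: 44646.3}
  training_groups:
    - label: nurses
      annual_total_cost:
        value: 885.5
        distribution: {kind: uniform, low: 708.4, high: 1052.6}
    - label: physicians
      annual_total_cost:
        value: 522.7
        distribution: {kind: uniform, low: 418.1, high: 627.3}
  device_annual: 0.0
# 141/yr PICU volume (ROI context); the published cost-per-error figure is
# consistent with a 74/yr ICER denominator (apparent row swap with
# epinephrine in the source tables), so the two are configured separately.
annual_administrations: 141
icer_administrations: 74
cat_e_cost_formulation: excess_only
wage_per_second: 0.0
psa:
  draws: 10000
  seed: 20190103
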