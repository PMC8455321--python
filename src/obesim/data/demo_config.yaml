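# Demo end-to-end run: synthetic epidemiology, synthetic demo trajectories,
# published delivery-cost schedules, all five interventions plus baseline.
seed: 1
cohort_size: 50000
entry_year: 2016
horizon_years: 30
discount_rate: 0.015
regain_rule: five_year
common_random_numbers: true
scenarios: [wmp1, vlcd_wmp1, wmp2, look_ahead, rygb]
epi_source: generate
epi_seed: 7
n_diseases: 12
severity: 1.0
trajectories: synthetic-demo
intervention_costs: packaged
out_dir: results/demo
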