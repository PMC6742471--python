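[settings]
discount_rate = 0.03
horizon_years = 10
owner_start_age = 44
dog_start_age = 2
dog_retirement_age = 10
perspective = societal
sek_per_usd = 8.538
rng_seed = 2019
psa_anchor = moment_matched
benefit_start_cycle = 1
include_unrelated_costs = false
retired_cost_growth = 1.0
retired_qaly_decay = 1.0
threshold_max = 150000
threshold_step = 2500
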