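dog_type,arm,total_cost_usd,total_qaly
physical_service,certified,1191121,2.79
physical_service,companion,1197080,2.51
diabetes_alert,certified,428137,6.26
diabetes_alert,companion,432653,6.20
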