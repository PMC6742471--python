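category,companion,certified,retired,alfa_companion,beta_companion,alfa_certified,beta_certified,alfa_retired,beta_retired
healthcare,9475,10001,9738,5,3752,12,1805,8,2677
municipal,3528,3095,3312,1,7292,1,6417,1,6855
informal_care,2414,1168,1791,12,432,13,198,12,315
productivity_loss,28900,27829,28364,15,4178,12,4822,13,4491
qaly_weight,0.656,0.674,0.665,36,19,24,12,,
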