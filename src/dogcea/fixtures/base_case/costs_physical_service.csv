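category,companion,certified,retired,alfa_companion,beta_companion,alfa_certified,beta_certified,alfa_retired,beta_retired
healthcare,8928,7530,8229,27,704,23,703,25,702
municipal,44588,47630,46109,10,9596,9,11232,9,10408
informal_care,4768,3503,4135,20,501,26,283,23,391
productivity_loss,66901,63859,65380,228,627,147,926,182,768
qaly_weight,0.226,0.351,0.309,14,39,29,53,,
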