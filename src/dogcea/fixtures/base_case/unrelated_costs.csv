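state,category,annual_value
companion,healthcare,0
companion,municipal,0
companion,informal_care,0
companion,productivity_loss,0
certified,healthcare,0
certified,municipal,0
certified,informal_care,0
certified,productivity_loss,0
retired_or_decert,healthcare,0
retired_or_decert,municipal,0
retired_or_decert,informal_care,0
retired_or_decert,productivity_loss,0
dog_dead,healthcare,0
dog_dead,municipal,0
dog_dead,informal_care,0
dog_dead,productivity_loss,0
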