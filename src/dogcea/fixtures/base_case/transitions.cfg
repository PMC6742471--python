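[transitions]
p_pass_minor = 0.9
p_pass_major = 0.9
p_pass_exam = 0.9
p_annual_decert = 0.02
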