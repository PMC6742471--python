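dog_type,category,certified,companion,difference
physical_service,healthcare,72804,84394,-11590
physical_service,municipal,431484,421479,10005
physical_service,informal_care,40909,45068,-4159
physical_service,productivity_loss,622396,632399,-10004
physical_service,dog,16536,13740,2796
physical_service,total,1184128,1197080,-12952
diabetes_alert,healthcare,76448,89566,-13118
diabetes_alert,municipal,31926,33348,-1422
diabetes_alert,informal_care,18720,22818,-4098
diabetes_alert,productivity_loss,269658,273181,-3523
diabetes_alert,dog,16536,13740,2796
diabetes_alert,total,413288,432653,-19365
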