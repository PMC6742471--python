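track,block,component,value,alfa,beta
companion,year1,purchase,1151,308,32
companion,year1,annual_upkeep,1332,92,10
companion,year1,total,2482,,
companion,year2,annual_upkeep,1332,92,10
companion,year2,total,1332,,
companion,subsequent,annual_upkeep,1332,92,10
companion,subsequent,total,1332,,
certified,year1,purchase,1151,308,32
certified,year1,annual_upkeep,1332,92,10
certified,year1,suitability_tests,193,,
certified,year1,total,2676,,
certified,year2,annual_upkeep,1332,92,10
certified,year2,training,7746,,
certified,year2,capes,211,,
certified,year2,total,9288,,
certified,subsequent,annual_upkeep,1332,92,10
certified,subsequent,maintenance_test,88,,
certified,subsequent,health_declaration,59,,
certified,subsequent,total,1478,,
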