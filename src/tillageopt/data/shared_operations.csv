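implement_id,power_class,work_rate_min_ha,timing,straw_only,sprays_as_passes,WW,WB,SB,WOSR,WFB
combine,combine,40.0,harvest,False,False,1,1,1,1,1
swather,swather,12.0,harvest,True,False,1,1,1,1,1
baler,baler,18.0,harvest,True,False,1,1,1,1,1
fert_spreader,small_tractor,8.0,spring,False,False,2,2,2,2,1
sprayer,small_tractor,6.0,spring,False,True,,,,,
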