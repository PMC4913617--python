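implement_id,power_class,work_rate_min_ha,timing,straw_only,sprays_as_passes,system,WW,WB,SB,WOSR,WFB
plough,large_tractor,70.0,establishment,False,False,CT,1,1,1,1,1
power_harrow,medium_tractor,67.0,establishment,False,False,CT,2,2,1,2,0
drill,medium_tractor,43.0,establishment,False,False,CT,1,1,1,1,1
plough,large_tractor,70.0,establishment,False,False,RP,1,1,1,0,0
power_harrow,medium_tractor,67.0,establishment,False,False,RP,2,2,1,0,0
medium_disc,medium_tractor,42.0,establishment,False,False,RP,0,0,0,2,2
drill,medium_tractor,43.0,establishment,False,False,RP,1,1,1,0,1
one_pass_cultivator,large_tractor,24.0,establishment,False,False,DRT,2,2,2,2,1
drill,medium_tractor,43.0,establishment,False,False,DRT,1,1,1,0,1
medium_disc,medium_tractor,42.0,establishment,False,False,SRT1,2,2,2,2,2
drill,medium_tractor,43.0,establishment,False,False,SRT1,1,1,1,0,1
spring_tine,medium_tractor,23.0,establishment,False,False,SRT2,2,2,2,2,2
drill,medium_tractor,43.0,establishment,False,False,SRT2,1,1,1,0,1
drill,medium_tractor,43.0,establishment,False,False,ZT,1,1,1,1,1
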