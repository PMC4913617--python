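id,machine_class,weight_kg,price_gbp,lifespan_h,fuel_l_h,spares_rate,insurance_rate,high_usage_cost,depreciation_schedule
small_tractor,small_tractor,3000.0,35000.0,3000.0,8.0,0.04,0.01,8.11,500.0:0.15;1500.0:0.27
medium_tractor,medium_tractor,5500.0,58000.0,3000.0,15.0,0.04,0.01,17.22,500.0:0.15;1500.0:0.27
large_tractor,large_tractor,8500.0,82000.0,3000.0,26.0,0.04,0.01,24.68,500.0:0.15;1500.0:0.27
combine,combine,12000.0,160000.0,3000.0,28.0,0.03,0.01,87.78,200.0:0.12;600.0:0.22
swather,swather,3500.0,40000.0,3000.0,12.0,0.03,0.01,35.29,200.0:0.12;600.0:0.22
baler,baler,2200.0,30000.0,3000.0,10.0,0.03,0.01,31.8,200.0:0.12;600.0:0.22
plough,implement,1850.0,22000.0,3000.0,0.0,0.03,0.01,0.0,100.0:0.1;600.0:0.18
power_harrow,implement,2500.0,28000.0,3000.0,0.0,0.03,0.01,0.0,100.0:0.1;600.0:0.18
one_pass_cultivator,implement,7350.0,62000.0,3000.0,0.0,0.03,0.01,0.0,100.0:0.1;600.0:0.18
medium_disc,implement,1720.0,26000.0,3000.0,0.0,0.03,0.01,0.0,100.0:0.1;600.0:0.18
spring_tine,implement,3500.0,27000.0,3000.0,0.0,0.03,0.01,0.0,100.0:0.1;600.0:0.18
drill,implement,3200.0,45000.0,3000.0,0.0,0.03,0.01,0.0,100.0:0.1;600.0:0.18
fert_spreader,implement,800.0,12000.0,3000.0,0.0,0.03,0.01,0.0,100.0:0.1;600.0:0.18
sprayer,implement,1200.0,30000.0,3000.0,0.0,0.03,0.01,0.0,100.0:0.1;600.0:0.18
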