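id,category,season,establishment_period,harvest_period,grain_yield,straw_yield,grain_energy_gj_t,straw_energy_gj_t,kcal_per_kg,n_rate,p_rate,k_rate,seed_cost,seed_energy_mj,drying_fuel_l_t
WW1,cereal,autumn,october,late_harvest,8.0,3.5,13.6,6.0,3340.0,220.0,60.0,90.0,60.0,180.0,9.0
WW2,cereal,autumn,october,late_harvest,7.2,3.2,13.6,6.0,3340.0,220.0,60.0,90.0,60.0,180.0,9.0
WWc,cereal,autumn,october,late_harvest,6.6,3.0,13.6,6.0,3340.0,220.0,60.0,90.0,60.0,180.0,9.0
WB,cereal,autumn,september,early_harvest,6.6,3.0,13.0,6.0,3320.0,130.0,60.0,80.0,55.0,170.0,9.0
SB,cereal,spring,spring,late_harvest,5.4,2.5,13.0,6.0,3320.0,110.0,50.0,70.0,50.0,160.0,9.0
WOSR,break,autumn,late_harvest,early_harvest,3.5,0.0,26.0,0.0,4000.0,190.0,55.0,50.0,60.0,60.0,14.0
WFB,break,autumn,october,late_harvest,4.0,0.0,14.0,0.0,3400.0,0.0,55.0,60.0,70.0,120.0,8.0
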