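emission_factors:
  n2o_ef: 0.016
  background_n2o_n: 1.4
  gwp_n2o: 298.0
  n_to_n2o: 1.5714285714285714
  steel_kgco2_kg: 1.56
  fuel_kgco2_l: 3.1
  n_manuf_kgco2_kg: 6.8
  p_manuf_kgco2_kg: 1.0
  k_manuf_kgco2_kg: 0.6
  pesticide_kgco2_spray: 6.3
energy_factors:
  steel_mj_kg: 23.0
  fuel_mj_l: 45.0
  n_manuf_mj_kg: 40.0
  p_manuf_mj_kg: 15.0
  k_manuf_mj_kg: 9.0
  pesticide_mj_spray: 150.0
resources:
  area_ha: 400.0
  interest_rate: 0.03
  spring_period: spring
n_response:
  0.5: 0.9
  0.75: 0.99
  1.0: 1.0
wosr_broadcast:
  CT: false
  RP: true
  DRT: true
  SRT1: true
  SRT2: true
  ZT: false
price_scalars:
  '2011':
    n_price_kg: 0.9375
    p_price_kg: 0.4
    k_price_kg: 0.5
    fuel_price_l: 0.645
    labour_wage: 10.0
    overhead_frac: 0.25
    labour_surcharge: 0.35
  '2014':
    n_price_kg: 0.75
    p_price_kg: 0.62
    k_price_kg: 0.49
    fuel_price_l: 0.645
    labour_wage: 10.19
    overhead_frac: 0.25
    labour_surcharge: 0.35
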