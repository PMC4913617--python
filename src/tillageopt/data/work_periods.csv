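id,labour_h,combine,small_tractor,medium_tractor,large_tractor
early_harvest,420.0,200.0,350.0,350.0,350.0
late_harvest,260.0,130.0,380.0,380.0,380.0
september,380.0,,400.0,400.0,400.0
october,390.0,,400.0,400.0,400.0
spring,1100.0,,800.0,800.0,800.0
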