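machine_class,fee_2011,fee_2014
small_tractor,25.01,23.9
medium_tractor,35.81,35.28
large_tractor,50.21,44.61
combine,121.0,123.48
swather,57.0,57.87
baler,45.63,53.51
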