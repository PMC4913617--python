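crop,category,sprays,cost_2011,cost_2014
WW1,fungicides,3,68.95,77.93
WW1,herbicides,3,36.01,44.04
WW1,growth regulators,2,22.54,23.5
WW1,insecticides,1,5.8,4.96
WW1,seed treatments and molluscicides,1,14.19,14.81
WW2,fungicides,3,68.95,77.93
WW2,herbicides,3,36.01,44.04
WW2,growth regulators,2,22.54,23.5
WW2,insecticides,1,5.8,4.96
WW2,seed treatments and molluscicides,1,16.09,16.79
WWc,fungicides,3,68.95,77.93
WWc,herbicides,3,36.01,44.04
WWc,growth regulators,2,22.54,23.5
WWc,insecticides,1,5.8,4.96
WWc,seed treatments and molluscicides,1,16.09,16.79
WB,fungicides,2,45.97,51.95
WB,herbicides,2,24.01,29.36
WB,growth regulators,1,11.27,11.75
WB,insecticides,1,5.8,4.96
WB,seed treatments and molluscicides,1,13.72,14.32
SB,fungicides,2,45.97,51.95
SB,herbicides,2,24.01,29.36
SB,seed treatments and molluscicides,1,15.61,16.29
WOSR,fungicides,2,29.14,22.13
WOSR,herbicides,3,89.43,80.36
WOSR,insecticides,2,12.87,11.5
WOSR,seed treatments and molluscicides,2,20.66,24.5
WFB,fungicides,2,37.01,30.33
WFB,herbicides,2,64.93,73.33
WFB,insecticides,2,12.87,13.25
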