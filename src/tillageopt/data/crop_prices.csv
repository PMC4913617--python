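species,product,price_2011,price_2014
WW,grain,172.36,144.56
WB,grain,164.42,122.64
SB,grain,164.42,122.64
WOSR,grain,374.08,290.49
WFB,grain,206.67,221.3
WW,straw,43.0,43.5
WB,straw,59.0,51.92
SB,straw,59.0,51.92
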