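gas,gwp100
CO2,1.0
CH4,27.2
N2O,273.0
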