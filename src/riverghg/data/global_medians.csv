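gas,median_saturation_pct
CO2,400.0
CH4,6324.0
N2O,146.0
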