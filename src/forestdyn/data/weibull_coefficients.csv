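region,a,b,c
GuianaShield,52.0,0.045,0.85
EastCentral,45.0,0.048,0.85
Western,41.0,0.050,0.85
BrazilianShield,38.0,0.052,0.85
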