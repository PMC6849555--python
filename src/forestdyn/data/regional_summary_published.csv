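variable,region,mean,se,n
agb,GuianaShield,211.91,5.03,110
agb,EastCentral,167.64,4.95,78
agb,Western,126.26,2.38,149
agb,BrazilianShield,107.73,4.48,76
wp,GuianaShield,3.51,0.13,41
wp,EastCentral,2.41,0.07,37
wp,Western,3.06,0.07,76
wp,BrazilianShield,2.40,0.15,13
mu,GuianaShield,1.66,0.16,41
mu,EastCentral,1.38,0.08,37
mu,Western,2.62,0.12,76
mu,BrazilianShield,3.19,0.38,13
wl,GuianaShield,3.06,0.44,41
wl,EastCentral,2.12,0.16,37
wl,Western,2.43,0.15,76
wl,BrazilianShield,1.57,0.12,13
wood_density,GuianaShield,0.69,0.00,110
wood_density,EastCentral,0.67,0.01,78
wood_density,Western,0.58,0.00,149
wood_density,BrazilianShield,0.61,0.01,76
basal_area,GuianaShield,29.10,0.49,110
basal_area,EastCentral,28.24,0.51,78
basal_area,Western,25.98,0.41,149
basal_area,BrazilianShield,22.73,0.66,76
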