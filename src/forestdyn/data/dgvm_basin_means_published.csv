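model,variable,mean,se,rmse
ORCHIDEE,agb,218.00,3.16,91.84
JULES,agb,137.93,2.09,76.98
INLAND,agb,125.43,1.35,61.36
LPJmL,agb,174.10,2.89,73.65
ORCHIDEE,wp,7.80,0.10,5.00
JULES,wp,4.05,0.09,1.89
INLAND,wp,7.46,0.11,4.73
LPJmL,wp,9.92,0.10,7.06
observations,agb,153.48,2.82,
observations,wp,2.97,0.06,
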