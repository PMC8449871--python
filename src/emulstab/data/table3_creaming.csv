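sample,combination,yield_pa,ads_um,lds_um,ads_pressure_pa,lds_pressure_pa,ci_ads_printed,ci_lds_printed
8,m/M/m/M/M,3.01e-1,12.49,34.23,4.03e-4,1.11e-3,747,270
10,m/M/M/M/m,2.35e0,11.67,34.25,3.80e-4,1.12e-3,6183,2107
11,M/m/m/M/M,2.96e-1,15.63,58.75,5.09e-4,1.91e-3,581,155
18,m/m/M/M/M,2.28e0,13.79,33.89,4.49e-4,1.10e-3,5076,2066
24,M/M/M/M/M,4.74e0,11.27,20,3.67e-4,6.51e-4,12914,7277
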