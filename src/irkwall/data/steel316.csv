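energy_mev,mu_over_rho,muen_over_rho,photoelectric_fraction
0.01,170.6,136.9,0.998947
0.015,57.08,48.96,0.996911
0.02,25.68,22.6,0.993253
0.03,8.176,7.251,0.979511
0.04,3.629,3.155,0.955287
0.05,1.958,1.638,0.919596
0.06,1.205,0.9555,0.873048
0.08,0.5952,0.4104,0.756329
0.1,0.3717,0.2177,0.62832
0.15,0.1964,0.07961,0.366727
0.2,0.146,0.04825,0.219407
0.3,0.1099,0.03361,0.0982909
0.4,0.094,0.03039,0.0554432
0.5,0.08414,0.02914,0.0364348
0.6,0.07704,0.02836,0.0264933
0.8,0.06699,0.02714,0.0166245
1,0.05995,0.02603,0.0122277
1.25,0.0535,0.02472,0.0104705
1.5,0.04883,0.0236,0.0148406
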