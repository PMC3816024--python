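energy_mev,mu_over_rho,muen_over_rho,photoelectric_fraction
0.01,3.357,3.026,0.938029
0.015,1.101,0.8324,0.814444
0.02,0.5714,0.3328,0.648701
0.03,0.3032,0.09645,0.359909
0.04,0.235,0.04599,0.20007
0.05,0.2074,0.03067,0.120605
0.06,0.1924,0.0253,0.0788661
0.08,0.1751,0.02302,0.0404187
0.1,0.1641,0.02368,0.0246637
0.15,0.1456,0.02657,0.0103692
0.2,0.1328,0.02872,0.00578242
0.3,0.1152,0.03099,0.00341707
0.4,0.1031,0.03185,0.00230206
0.5,0.0941,0.03206,0.00185009
0.6,0.08701,0.03191,0.00140853
0.8,0.07641,0.03116,0.00119441
1,0.0687,0.03015,0.00140112
1.25,0.06143,0.02882,0.00160172
1.5,0.05591,0.02755,0.00320574
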