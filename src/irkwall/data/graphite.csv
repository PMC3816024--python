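energy_mev,mu_over_rho,muen_over_rho,photoelectric_fraction
0.01,2.373,2.078,0.918806
0.015,0.8071,0.5627,0.765567
0.02,0.442,0.2238,0.579391
0.03,0.2562,0.06614,0.298423
0.04,0.2076,0.03343,0.161359
0.05,0.1871,0.02397,0.0971772
0.06,0.1753,0.02098,0.063669
0.08,0.161,0.02037,0.0334473
0.1,0.1514,0.02147,0.0209145
0.15,0.1347,0.02449,0.00928108
0.2,0.1229,0.02655,0.00502742
0.3,0.1066,0.0287,0.00254755
0.4,0.09546,0.0295,0.0020247
0.5,0.08715,0.02969,0.00183696
0.6,0.08058,0.02956,0.00135016
0.8,0.07076,0.02885,0.00108894
1,0.06361,0.02792,0.00113706
1.25,0.0569,0.02669,0.00171268
1.5,0.05179,0.02551,0.00337313
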