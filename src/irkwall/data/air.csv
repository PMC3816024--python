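energy_mev,mu_over_rho,muen_over_rho,photoelectric_fraction
0.01,5.12,4.742,0.962395
0.015,1.614,1.334,0.882851
0.02,0.7779,0.5389,0.761179
0.03,0.3538,0.1537,0.492317
0.04,0.2485,0.06833,0.29988
0.05,0.208,0.04098,0.188463
0.06,0.1875,0.03041,0.125206
0.08,0.1662,0.02407,0.0643445
0.1,0.1541,0.02325,0.0387432
0.15,0.1356,0.02496,0.0165462
0.2,0.1233,0.02672,0.00895009
0.3,0.1067,0.02872,0.00418057
0.4,0.09549,0.02949,0.00303723
0.5,0.08712,0.02966,0.00219284
0.6,0.08055,0.02953,0.00167818
0.8,0.07074,0.02882,0.0015066
1,0.06358,0.02789,0.00136593
1.25,0.05687,0.02666,0.00188588
1.5,0.05175,0.02547,0.00330161
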