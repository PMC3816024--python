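energy_mev,mu_over_rho,muen_over_rho,photoelectric_fraction
0.01,108,86.4,0.998569
0.015,68,54.4,0.997769
0.02,73,59.86,0.997958
0.03,25.5,21.675,0.994347
0.04,12,10.32,0.988365
0.05,6.7,5.762,0.979782
0.06,4.2,3.57,0.968661
0.076,2.3,1.909,0.945184
0.0762,9.3,6.51,0.98645
0.08,8,5.76,0.984401
0.1,4.8,3.36,0.975235
0.15,1.74,0.957,0.938497
0.2,0.865,0.346,0.886636
0.3,0.354,0.07788,0.759134
0.4,0.207,0.03105,0.630937
0.5,0.147,0.01764,0.525451
0.6,0.115,0.01265,0.438858
0.8,0.0837,0.00837,0.322797
1,0.068,0.00646,0.250706
1.25,0.0569,0.005121,0.199456
1.5,0.0508,0.0044704,0.185212
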