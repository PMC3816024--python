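energy_mev,intensity_per_decay
0.061486,0.012
0.065122,0.0263
0.066831,0.0446
0.075749,0.0153
0.077831,0.00414
0.136343,0.00183
0.201311,0.00473
0.205795,0.0334
0.283267,0.00266
0.295957,0.2871
0.308455,0.297
0.316506,0.8286
0.374485,0.00726
0.416469,0.0067
0.468069,0.4784
0.484575,0.03189
0.489060,0.00438
0.588581,0.04522
0.604411,0.08216
0.612462,0.0534
0.884537,0.00293
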