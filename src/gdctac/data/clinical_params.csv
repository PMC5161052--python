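case,t_A_min,a,b_per_min,alpha,beta_per_min,S_counts,fit_err_pct,noise_pct,one_minus_r2_pct
1L,0.195,0.846,0.909,0.8577,0.001849,3529000,1.713,1.174,0.534
1R,0.334,3.733,5.211,0.8661,0.004081,2319000,1.914,1.094,0.350
1T,0.277,1.631,2.060,0.8645,0.003106,5222000,1.421,0.800,0.271
2L,0.340,1.351,1.692,0.9408,0.004445,2027000,1.690,1.183,0.630
2R,0.282,0.995,0.928,0.8668,0.001240,6510000,1.353,1.022,0.395
2T,0.307,1.127,1.203,0.8998,0.002652,6625000,1.019,0.773,0.239
3L,0.306,7.878,11.644,0.8918,0.002029,3201000,1.801,1.225,0.818
3R,0.425,3.082,4.520,0.8942,0.002863,3296000,1.026,1.060,0.189
3T,0.374,6.470,9.842,0.8947,0.002554,6287000,0.988,0.801,0.224
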