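row,T_C,C_wpi_pct,P_MPa,pH,solid_yield,solid_yield_sd,x_alpha_solid,x_alpha_solid_sd,x_beta_solid,x_gmp_solid,x_minor_solid,rec_alpha_solid,rec_alpha_solid_sd,purity_ratio,x_beta_liquid,rec_beta_liquid,rec_beta_liquid_sd,x_gmp_liquid,rec_gmp_liquid
1,60,10,5.5,5.0,0.211,0.017,0.539,0.015,0.280,0.055,0.126,0.633,0.068,5.3,,0.880,0.009,,0.928
2,60,10,8.3,4.9,0.209,0.025,0.519,0.021,0.282,0.042,0.158,0.601,0.095,5.1,0.681,0.881,0.012,0.220,0.948
3,60,10,31.0,4.6,0.289,0.008,0.539,0.016,0.303,0.036,0.121,0.866,0.043,4.9,0.695,0.823,0.006,0.235,0.936
4,60,5,8.3,4.7,0.236,0.005,0.610,0.027,0.240,0.022,0.129,0.801,0.051,7.0,,0.886,0.007,,0.968
5,60,5,31.0,4.4,0.283,0.003,0.555,0.008,0.286,0.020,0.140,0.873,0.022,5.3,0.702,0.837,0.008,0.245,0.966
6,62,10,5.5,5.0,0.224,0.006,0.570,0.027,0.250,0.038,0.142,0.711,0.048,6.3,0.689,0.887,0.018,0.231,0.947
7,65,10,5.5,5.0,0.297,0.015,0.529,0.025,0.344,0.064,0.063,0.874,0.002,4.2,,0.793,0.023,,0.883
8,65,10,8.3,4.9,0.350,0.001,0.447,0.033,0.388,0.044,0.121,0.869,0.066,3.2,,0.726,0.000,,0.914
9,65,10,31.0,4.6,0.404,0.043,0.435,0.017,0.452,0.035,0.078,0.977,0.077,2.7,0.650,0.632,0.056,0.302,0.897
10,65,5,8.3,4.7,0.293,0.013,0.519,0.023,0.350,0.021,0.110,0.843,0.001,4.1,,0.793,0.028,,0.962
11,65,5,31.0,4.4,0.365,0.022,0.388,0.011,0.494,0.023,0.095,0.787,0.065,2.2,0.641,0.636,0.027,0.287,0.953
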