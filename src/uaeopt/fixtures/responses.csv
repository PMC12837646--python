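sample_id,TPC,TPC_sd,TFC,TFC_sd,DPPH,DPPH_sd,ABTS,ABTS_sd,CUPRAC,CUPRAC_sd,FRAP,FRAP_sd,MC,MC_sd,PM,PM_sd,AChE,AChE_sd,BChE,BChE_sd,Tyrosinase,Tyrosinase_sd,alpha-amylase,alpha-amylase_sd,alpha-glucosidase,alpha-glucosidase_sd
1,11.184,0.103,0.804,0.034,16.634,0.521,21.335,0.432,31.314,0.276,17.485,0.044,16.389,0.610,0.532,0.028,1.973,0.077,1.755,0.201,52.258,1.345,0.833,0.010,1.070,0.066
2,10.793,0.159,1.001,0.025,17.709,0.509,22.707,0.071,33.100,0.110,21.161,0.217,17.456,0.502,0.441,0.012,1.926,0.046,2.094,0.152,54.097,0.383,0.739,0.026,0.826,0.019
3,13.301,0.473,1.648,0.063,27.054,0.144,34.898,0.937,43.283,0.530,28.328,0.131,14.004,0.586,0.591,0.014,2.540,0.020,1.789,0.089,54.720,0.516,0.863,0.008,1.114,0.100
4,10.589,0.070,0.858,0.048,17.635,0.593,22.765,0.497,31.747,0.894,17.776,0.045,15.740,0.253,0.522,0.020,1.948,0.058,2.141,0.045,53.661,0.405,0.785,0.022,1.090,0.042
5,9.372,0.358,1.023,0.046,15.530,0.576,15.503,0.280,29.701,0.261,19.310,0.120,18.501,1.477,0.440,0.050,2.213,0.060,2.078,0.103,52.503,0.733,0.862,0.021,0.924,0.015
6,16.494,0.149,2.103,0.006,32.695,0.568,46.764,0.315,57.285,1.619,38.900,1.298,19.140,0.148,0.542,0.032,2.320,0.019,2.058,0.016,55.453,0.201,0.738,0.019,0.965,0.085
7,8.692,0.507,0.880,0.049,16.261,0.428,15.380,0.649,30.010,0.354,17.596,0.432,12.929,0.577,0.536,0.022,2.242,0.028,2.360,0.044,54.470,0.892,0.852,0.012,0.864,0.119
8,10.970,0.191,1.139,0.020,22.457,0.368,32.279,0.265,32.648,0.859,22.445,0.473,17.188,0.293,0.394,0.021,1.579,0.085,1.545,0.056,52.718,0.571,0.827,0.060,0.742,0.086
9,14.955,0.328,1.563,0.042,23.886,0.708,32.856,0.768,43.669,0.903,28.556,0.313,17.971,0.005,0.594,0.005,1.996,0.048,2.160,0.134,54.086,0.420,0.816,0.033,0.706,0.086
10,15.213,0.316,1.617,0.026,26.829,0.206,38.387,0.758,42.129,0.608,28.546,0.434,18.001,0.452,0.517,0.001,1.817,0.030,1.388,0.014,53.475,0.772,0.827,0.008,0.988,0.125
11,12.236,0.224,1.765,0.043,22.619,0.579,26.854,0.155,42.861,0.406,26.130,0.410,20.374,0.283,0.580,0.019,2.194,0.025,1.904,0.097,52.305,0.475,0.902,0.019,1.123,0.018
12,11.475,0.026,1.263,0.075,21.935,0.581,29.346,1.007,35.250,0.255,22.747,0.262,17.474,0.827,0.482,0.034,1.881,0.032,1.498,0.139,50.553,0.615,0.844,0.008,1.016,0.082
13,9.982,0.425,1.180,0.037,19.428,0.589,23.197,0.167,29.870,0.108,19.527,0.600,18.489,0.900,0.424,0.060,1.740,0.087,1.451,0.080,51.374,0.663,0.895,0.009,1.019,0.153
14,9.174,0.071,0.952,0.050,17.980,0.471,16.036,0.397,30.639,0.252,19.027,0.488,18.109,0.440,0.461,0.049,2.357,0.070,1.994,0.075,52.666,0.559,0.889,0.012,0.929,0.082
15,14.176,0.286,1.295,0.026,21.100,0.818,22.209,0.203,41.530,0.451,24.499,0.212,8.611,0.503,0.740,0.035,2.170,0.020,1.847,0.138,43.139,1.983,0.766,0.021,0.902,0.063
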