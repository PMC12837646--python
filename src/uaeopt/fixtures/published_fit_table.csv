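response,chi2,rmse,mbe,mpe,sse,aard,r2
TPC,0.007,0.078,0.004,0.557,0.091,0.975,0.999
TFC,0.000,0.009,0.000,0.666,0.001,0.160,0.999
DPPH,0.019,0.129,0.014,0.545,0.248,2.507,0.999
ABTS,0.097,0.291,0.114,1.064,1.072,3.342,0.999
CUPRAC,0.061,0.230,0.026,0.492,0.783,2.841,0.999
FRAP,0.027,0.154,0.019,0.572,0.349,2.356,0.999
MC,0.003,0.050,0.008,0.244,0.037,1.069,0.999
PM,0.000,0.003,-0.001,0.537,0.000,0.066,0.999
AChE,0.000,0.008,0.002,0.353,0.001,0.137,0.999
BChE,0.000,0.010,0.001,0.485,0.001,0.135,0.999
Tyrosinase,0.005,0.068,-0.016,0.112,0.065,0.994,0.999
alpha-amylase,0.000,0.001,0.000,0.142,0.000,0.018,0.999
alpha-glucosidase,0.000,0.005,0.000,0.402,0.000,0.054,0.999
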