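{
 "model_id": "ANN2",
 "architecture": [
  3,
  10,
  6
 ],
 "input_names": [
  "time",
  "temperature",
  "ratio"
 ],
 "output_names": [
  "DPPH",
  "ABTS",
  "CUPRAC",
  "FRAP",
  "MC",
  "PM"
 ],
 "hidden_activation": "tanh",
 "output_activation": "tanh",
 "W1_shape": [
  10,
  3
 ],
 "W1": [
  [
   -14.977,
   3.018,
   10.497
  ],
  [
   3.657,
   0.938,
   0.918
  ],
  [
   2.872,
   1.333,
   3.496
  ],
  [
   0.461,
   -4.795,
   5.038
  ],
  [
   6.655,
   3.146,
   0.083
  ],
  [
   -18.666,
   11.988,
   2.971
  ],
  [
   -0.52,
   -1.591,
   -0.142
  ],
  [
   -10.25,
   -2.983,
   -3.607
  ],
  [
   -7.01,
   -8.548,
   6.351
  ],
  [
   -0.021,
   -3.227,
   3.393
  ]
 ],
 "B1": [
  0.137,
  -1.069,
  -3.615,
  3.482,
  -9.731,
  -1.995,
  2.863,
  6.613,
  1.041,
  -0.487
 ],
 "W2_shape": [
  6,
  10
 ],
 "W2": [
  [
   4.276,
   -3.903,
   -2.66,
   -1.743,
   -1.045,
   -3.002,
   0.357,
   -3.551,
   -5.818,
   5.456
  ],
  [
   4.11,
   -4.917,
   -2.961,
   -1.942,
   -1.443,
   -2.877,
   -0.072,
   -4.084,
   -6.452,
   6.106
  ],
  [
   4.456,
   -3.557,
   -2.846,
   -1.574,
   -0.472,
   -3.038,
   0.827,
   -3.632,
   -5.526,
   5.181
  ],
  [
   3.428,
   -1.782,
   -1.663,
   -0.924,
   0.568,
   -2.27,
   3.905,
   -2.277,
   -3.581,
   3.165
  ],
  [
   -0.251,
   -2.107,
   -0.451,
   -4.768,
   0.937,
   0.167,
   2.405,
   -0.776,
   -1.791,
   1.581
  ],
  [
   1.252,
   4.388,
   0.96,
   4.212,
   7.144,
   -0.845,
   3.328,
   1.751,
   2.877,
   -2.812
  ]
 ],
 "B2": [
  1.742,
  2.459,
  1.431,
  -1.614,
  4.779,
  -1.782
 ],
 "summary": {
  "train_perf": 0.999,
  "test_perf": 0.996,
  "valid_perf": 0.993,
  "train_error": 1.233,
  "test_error": 1.555,
  "valid_error": 2.999,
  "training_algorithm": "BFGS 10000",
  "error_function": "SOS"
 }
}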