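{
 "model_id": "ANN3",
 "architecture": [
  3,
  10,
  5
 ],
 "input_names": [
  "time",
  "temperature",
  "ratio"
 ],
 "output_names": [
  "AChE",
  "BChE",
  "Tyrosinase",
  "alpha-amylase",
  "alpha-glucosidase"
 ],
 "hidden_activation": "logistic",
 "output_activation": "identity",
 "W1_shape": [
  10,
  3
 ],
 "W1": [
  [
   -3.656,
   3.569,
   -8.416
  ],
  [
   -3.576,
   3.666,
   0.785
  ],
  [
   -3.421,
   3.869,
   -4.395
  ],
  [
   -8.473,
   7.991,
   0.029
  ],
  [
   -2.593,
   5.218,
   0.998
  ],
  [
   -2.336,
   6.572,
   -6.147
  ],
  [
   -4.079,
   5.171,
   -0.617
  ],
  [
   -1.876,
   9.862,
   -2.914
  ],
  [
   -2.826,
   5.198,
   -5.13
  ],
  [
   -6.256,
   13.951,
   -4.205
  ]
 ],
 "B1": [
  1.173,
  2.266,
  0.951,
  -1.431,
  0.198,
  -1.555,
  -1.709,
  -3.46,
  -1.273,
  0.145
 ],
 "W2_shape": [
  5,
  10
 ],
 "W2": [
  [
   -0.027,
   1.432,
   -0.714,
   -2.462,
   -0.7,
   2.516,
   4.286,
   -1.351,
   -2.748,
   0.838
  ],
  [
   -2.386,
   3.737,
   -1.091,
   -0.667,
   -3.849,
   2.436,
   0.886,
   -2.347,
   0.905,
   3.006
  ],
  [
   -2.412,
   -0.178,
   2.002,
   -2.384,
   0.145,
   1.909,
   2.855,
   -2.332,
   -0.977,
   0.718
  ],
  [
   2.507,
   -2.035,
   0.593,
   -0.135,
   2.128,
   1.838,
   1.083,
   1.898,
   -4.851,
   -2.718
  ],
  [
   -2.729,
   2.291,
   3.296,
   -3.347,
   -0.453,
   -2.418,
   2.054,
   0.033,
   2.884,
   -0.795
  ]
 ],
 "B2": [
  -0.399,
  -0.461,
  0.81,
  0.894,
  -0.695
 ],
 "summary": {
  "train_perf": 0.999,
  "test_perf": 0.999,
  "valid_perf": 0.995,
  "train_error": 1.688,
  "test_error": 1.998,
  "valid_error": 2.999,
  "training_algorithm": "BFGS 299",
  "error_function": "SOS"
 }
}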