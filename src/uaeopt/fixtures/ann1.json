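{
 "model_id": "ANN1",
 "architecture": [
  3,
  9,
  2
 ],
 "input_names": [
  "time",
  "temperature",
  "ratio"
 ],
 "output_names": [
  "TPC",
  "TFC"
 ],
 "hidden_activation": "tanh",
 "output_activation": "identity",
 "W1_shape": [
  9,
  3
 ],
 "W1": [
  [
   1.829,
   0.727,
   1.245
  ],
  [
   0.046,
   -4.094,
   1.314
  ],
  [
   2.049,
   -1.845,
   -2.82
  ],
  [
   -0.616,
   -0.996,
   -0.821
  ],
  [
   2.11,
   -2.036,
   -2.044
  ],
  [
   -2.953,
   -0.604,
   -0.676
  ],
  [
   -2.765,
   -0.21,
   0.034
  ],
  [
   3.182,
   -0.819,
   -2.235
  ],
  [
   -1.494,
   0.609,
   -1.004
  ]
 ],
 "B1": [
  -2.096,
  -1.565,
  1.896,
  0.695,
  1.592,
  1.396,
  0.093,
  1.054,
  0.359
 ],
 "W2_shape": [
  2,
  9
 ],
 "W2": [
  [
   0.182,
   -1.142,
   -0.886,
   0.898,
   1.159,
   -1.269,
   1.3,
   -0.56,
   -0.347
  ],
  [
   1.034,
   -0.573,
   -1.155,
   0.79,
   1.744,
   -0.006,
   -0.67,
   -1.067,
   0.513
  ]
 ],
 "B2": [
  0.433,
  -0.045
 ],
 "summary": {
  "train_perf": 0.999,
  "test_perf": 0.997,
  "valid_perf": 0.995,
  "train_error": 1.276,
  "test_error": 1.778,
  "valid_error": 1.969,
  "training_algorithm": "BFGS 122",
  "error_function": "SOS"
 }
}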