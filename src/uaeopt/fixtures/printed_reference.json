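{
 "correlations": {
  "FRAP~CUPRAC": 0.973,
  "DPPH~FRAP": 0.9572,
  "TPC~PM": 0.5517,
  "TFC~PM": 0.3561
 },
 "correlation_core_min": 0.83,
 "pca": {
  "PC1_pct": 46.15,
  "PC2_pct": 15.66,
  "PC1+PC2_pct": 61.81
 },
 "standard_score": {
  "best_sample": 6,
  "score": 0.794
 },
 "optimum": {
  "time": 20,
  "temperature": 50,
  "ratio": 20,
  "TPC": 16.494,
  "TFC": 2.103
 },
 "training_r2": {
  "ANN1": 0.999,
  "ANN2": 0.999,
  "ANN3": 0.999
 },
 "hca": {
  "singleton_sample": 6,
  "min_singleton_height": 100.0
 },
 "ranges": {
  "TPC": [
   8.692,
   16.494
  ],
  "TFC": [
   0.804,
   2.103
  ]
 }
}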