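{
 "TPC": "mg GAE/g",
 "TFC": "mg RE/g",
 "DPPH": "mg TE/g",
 "ABTS": "mg TE/g",
 "CUPRAC": "mg TE/g",
 "FRAP": "mg TE/g",
 "MC": "mg EDTAE/g",
 "PM": "mmol TE/g",
 "AChE": "mg GALAE/g",
 "BChE": "mg GALAE/g",
 "Tyrosinase": "mg KAE/g",
 "alpha-amylase": "mmol ACAE/g",
 "alpha-glucosidase": "mmol ACAE/g"
}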