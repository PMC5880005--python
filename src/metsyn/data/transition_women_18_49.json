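{
 "stratum": "women_18_49",
 "description": "Published annual transition probabilities (percent) of the 12-state metabolic-syndrome Markov model, women aged 18-49; mean of five per-cycle proportions from a 6-year check-up cohort.",
 "units": "percent",
 "states": [
  "NONE",
  "OW",
  "HTN",
  "DYS",
  "HYP",
  "OW_HTN",
  "OW_DYS",
  "OW_HYP",
  "HTN_DYS",
  "HTN_HYP",
  "DYS_HYP",
  "MS"
 ],
 "percent": [
  [
   78.21,
   7.15,
   2.44,
   8.45,
   0.6,
   0.46,
   1.3,
   0.01,
   0.49,
   0.06,
   0.2,
   0.63
  ],
  [
   18.51,
   52.01,
   0.95,
   4.32,
   0.63,
   4.98,
   15.19,
   0.21,
   0.0,
   0.0,
   0.12,
   3.07
  ],
  [
   0.0,
   0.0,
   74.82,
   0.0,
   0.0,
   4.98,
   0.0,
   0.0,
   15.39,
   1.45,
   0.0,
   3.37
  ],
  [
   39.9,
   1.37,
   2.04,
   46.36,
   0.0,
   0.55,
   4.62,
   0.0,
   2.87,
   0.0,
   0.56,
   1.72
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   67.46,
   0.0,
   0.0,
   0.54,
   0.0,
   13.09,
   14.69,
   4.22
  ],
  [
   0.0,
   0.0,
   17.75,
   0.0,
   0.0,
   58.62,
   0.0,
   0.0,
   4.67,
   2.64,
   0.0,
   16.32
  ],
  [
   9.33,
   21.16,
   0.0,
   12.99,
   0.34,
   4.12,
   42.34,
   0.0,
   0.62,
   0.0,
   1.51,
   7.57
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   17.37,
   0.0,
   0.0,
   58.88,
   0.0,
   0.97,
   1.36,
   21.42
  ],
  [
   0.0,
   0.0,
   23.2,
   0.0,
   0.0,
   2.98,
   0.0,
   0.0,
   62.53,
   0.43,
   0.0,
   10.87
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   79.44,
   0.0,
   20.56
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   25.91,
   0.0,
   0.0,
   5.26,
   0.0,
   3.9,
   48.53,
   16.4
  ],
  [
   0.0,
   0.0,
   13.52,
   0.0,
   3.9,
   11.34,
   0.0,
   2.36,
   3.36,
   3.64,
   1.23,
   60.64
  ]
 ],
 "row_checksums": [
  100.0,
  99.99,
  100.01,
  99.99,
  100.0,
  100.0,
  99.98,
  100.0,
  100.01,
  100.0,
  100.0,
  99.99
 ]
}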