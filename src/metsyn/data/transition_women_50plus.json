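{
 "stratum": "women_50plus",
 "description": "Published annual transition probabilities (percent) of the 12-state metabolic-syndrome Markov model, women aged 50 and over; mean of five per-cycle proportions from a 6-year check-up cohort.",
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
   64.86,
   4.01,
   8.17,
   11.3,
   2.04,
   0.51,
   2.19,
   0.65,
   2.69,
   0.4,
   1.67,
   1.5
  ],
  [
   12.08,
   40.3,
   0.78,
   5.38,
   2.46,
   11.5,
   15.7,
   4.24,
   0.0,
   0.0,
   0.62,
   6.93
  ],
  [
   0.0,
   0.0,
   56.31,
   0.0,
   0.0,
   8.6,
   0.0,
   0.0,
   23.91,
   5.02,
   0.0,
   6.17
  ],
  [
   23.89,
   1.96,
   1.92,
   52.69,
   2.22,
   1.33,
   3.11,
   0.0,
   5.32,
   0.0,
   1.96,
   5.61
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   55.98,
   0.0,
   0.0,
   0.0,
   0.0,
   13.05,
   19.09,
   11.87
  ],
  [
   0.0,
   0.0,
   6.47,
   0.0,
   0.0,
   67.58,
   0.0,
   0.0,
   4.83,
   0.54,
   0.0,
   20.58
  ],
  [
   6.22,
   13.99,
   0.0,
   6.42,
   0.0,
   5.09,
   48.73,
   0.0,
   2.29,
   0.0,
   0.0,
   17.27
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   10.61,
   0.0,
   0.0,
   50.35,
   0.0,
   4.74,
   7.12,
   27.18
  ],
  [
   0.0,
   0.0,
   20.05,
   0.0,
   0.0,
   0.32,
   0.0,
   0.0,
   61.15,
   3.42,
   0.0,
   15.07
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
   75.01,
   0.0,
   24.99
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   9.62,
   0.0,
   0.0,
   0.0,
   0.0,
   2.09,
   63.02,
   25.28
  ],
  [
   0.0,
   0.0,
   6.04,
   0.0,
   2.14,
   9.63,
   0.0,
   0.58,
   4.8,
   0.95,
   0.35,
   75.52
  ]
 ],
 "row_checksums": [
  99.99,
  99.99,
  100.01,
  100.01,
  99.99,
  100.0,
  100.01,
  100.0,
  100.01,
  100.0,
  100.01,
  100.01
 ]
}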