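{
 "stratum": "men_50plus",
 "description": "Published annual transition probabilities (percent) of the 12-state metabolic-syndrome Markov model, men aged 50 and over; mean of five per-cycle proportions from a 6-year check-up cohort.",
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
   60.42,
   5.09,
   12.11,
   11.44,
   2.26,
   1.29,
   2.0,
   0.62,
   1.68,
   0.74,
   0.81,
   1.54
  ],
  [
   8.97,
   40.96,
   1.65,
   1.62,
   0.0,
   14.66,
   18.76,
   3.47,
   0.21,
   0.0,
   0.0,
   9.7
  ],
  [
   0.0,
   0.0,
   62.64,
   0.0,
   0.0,
   7.29,
   0.0,
   0.0,
   16.48,
   6.03,
   0.0,
   7.56
  ],
  [
   23.89,
   2.32,
   3.17,
   41.93,
   0.0,
   0.9,
   5.23,
   0.0,
   11.27,
   0.0,
   2.66,
   8.63
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   47.32,
   0.0,
   0.0,
   4.79,
   0.0,
   20.63,
   12.86,
   14.41
  ],
  [
   0.0,
   0.0,
   9.28,
   0.0,
   0.0,
   60.14,
   0.0,
   0.0,
   1.86,
   1.24,
   0.0,
   27.49
  ],
  [
   3.1,
   13.77,
   0.0,
   3.78,
   0.25,
   3.74,
   52.87,
   1.47,
   1.87,
   0.0,
   0.49,
   18.65
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   7.03,
   0.0,
   0.0,
   56.4,
   0.0,
   2.34,
   2.73,
   31.49
  ],
  [
   0.0,
   0.0,
   21.42,
   0.0,
   0.0,
   2.76,
   0.0,
   0.0,
   57.0,
   2.6,
   0.0,
   16.22
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
   73.47,
   0.0,
   26.53
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   20.75,
   0.0,
   0.0,
   1.16,
   0.0,
   1.39,
   52.44,
   24.26
  ],
  [
   0.0,
   0.0,
   0.83,
   0.0,
   0.1,
   10.74,
   0.0,
   3.07,
   2.4,
   1.82,
   0.6,
   80.43
  ]
 ],
 "row_checksums": [
  100.0,
  100.0,
  100.0,
  100.0,
  100.01,
  100.01,
  99.99,
  99.99,
  100.0,
  100.0,
  100.0,
  99.99
 ]
}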