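{
 "stratum": "men_18_49",
 "description": "Published annual transition probabilities (percent) of the 12-state metabolic-syndrome Markov model, men aged 18-49; mean of five per-cycle proportions from a 6-year check-up cohort.",
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
   66.44,
   10.15,
   4.19,
   10.78,
   0.67,
   1.47,
   3.28,
   0.13,
   1.13,
   0.12,
   0.36,
   1.28
  ],
  [
   7.14,
   47.19,
   1.12,
   2.7,
   0.16,
   8.78,
   22.66,
   1.23,
   0.32,
   0.03,
   0.03,
   8.63
  ],
  [
   0.0,
   0.0,
   63.81,
   0.0,
   0.0,
   9.61,
   0.0,
   0.0,
   16.29,
   2.08,
   0.0,
   8.21
  ],
  [
   23.04,
   3.14,
   2.85,
   48.02,
   0.0,
   1.18,
   9.47,
   0.0,
   4.96,
   0.0,
   1.71,
   5.61
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   45.66,
   0.0,
   0.0,
   6.24,
   0.0,
   7.99,
   28.34,
   11.76
  ],
  [
   0.0,
   0.0,
   7.24,
   0.0,
   0.0,
   66.12,
   0.0,
   0.0,
   2.43,
   0.3,
   0.0,
   23.91
  ],
  [
   3.14,
   15.08,
   0.0,
   4.86,
   0.0,
   2.44,
   58.53,
   0.64,
   0.41,
   0.0,
   0.06,
   14.83
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   7.74,
   0.0,
   0.0,
   60.11,
   0.0,
   1.98,
   2.97,
   27.2
  ],
  [
   0.0,
   0.0,
   26.15,
   0.0,
   0.0,
   5.68,
   0.0,
   0.0,
   53.36,
   0.99,
   0.0,
   13.82
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
   79.2,
   0.0,
   20.8
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   24.62,
   0.0,
   0.0,
   0.42,
   0.0,
   4.87,
   56.02,
   14.07
  ],
  [
   0.0,
   0.0,
   1.91,
   0.0,
   0.23,
   11.36,
   0.0,
   4.04,
   3.4,
   3.19,
   0.64,
   75.25
  ]
 ],
 "row_checksums": [
  100.0,
  99.99,
  100.0,
  99.98,
  99.99,
  100.0,
  99.99,
  100.0,
  100.0,
  100.0,
  100.0,
  100.02
 ],
 "notes": "The isolated-hyperglycemia (HYP) row as published contains a typographically corrupt cell '0.6.24'; it is resolved here as 6.24 in the OW_HYP column, which makes the row sum 99.99 and matches the nonzero analogous cell in the other strata. transitions.load_printed_matrix(alternate_corrupt_cell=True) moves it to the OW_DYS column instead."
}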