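{
 "description": "Published follow-up summary of the same cohort: visit counts and outcome counts at baseline and at each of five annual follow-up visits.",
 "years": [
  0,
  1,
  2,
  3,
  4,
  5
 ],
 "n": [
  21777,
  19330,
  11226,
  8652,
  7918,
  4776
 ],
 "age_mean": [
  43.98,
  44.72,
  45.57,
  47.28,
  48.47,
  49.96
 ],
 "age_sd": [
  12.36,
  12.36,
  11.62,
  11.86,
  11.35,
  11.31
 ],
 "counts": {
  "sex_male": [
   14250,
   12504,
   7522,
   5432,
   4918,
   3086
  ],
  "overweight_obesity": [
   8964,
   8312,
   5031,
   3732,
   3542,
   2174
  ],
  "hypertension": [
   6267,
   7125,
   4781,
   4025,
   3864,
   2478
  ],
  "dyslipidemia": [
   8168,
   8208,
   4880,
   3906,
   4301,
   2927
  ],
  "hyperglycemia": [
   2297,
   2530,
   1780,
   1516,
   1555,
   1019
  ],
  "ms": [
   3289,
   3852,
   2632,
   2328,
   2361,
   1564
  ]
 },
 "published_pct": {
  "sex_male": [
   65.44,
   64.69,
   67.0,
   62.76,
   62.11,
   64.61
  ],
  "overweight_obesity": [
   41.16,
   43.0,
   44.82,
   43.13,
   44.73,
   45.52
  ],
  "hypertension": [
   28.78,
   36.86,
   42.59,
   46.52,
   48.86,
   51.88
  ],
  "dyslipidemia": [
   37.51,
   42.46,
   43.47,
   45.15,
   54.32,
   61.29
  ],
  "hyperglycemia": [
   10.55,
   13.09,
   15.86,
   17.52,
   19.64,
   21.34
  ],
  "ms": [
   15.1,
   19.93,
   23.45,
   26.9,
   29.82,
   32.75
  ]
 },
 "notes": "Four published percentages disagree with their own counts by 0.01-0.06 points: sex_male at follow-up years 2 and 3 (counts give 67.01 and 62.78, published 67.00 and 62.76), hypertension at year 4 (48.80 vs published 48.86) and ms at year 3 (26.91 vs published 26.90)."
}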