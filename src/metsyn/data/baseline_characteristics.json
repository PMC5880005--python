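{
 "description": "Published baseline characteristics of a 6-year check-up cohort (n=21,777), stratified by sex and fine age band: group sizes, age mean/sd, and counts of each CDS component and of metabolic syndrome, with the published chi-square statistic comparing the four age bands within each sex.",
 "age_bands": [
  "18-39",
  "40-49",
  "50-59",
  "60+"
 ],
 "outcomes": [
  "overweight_obesity",
  "hypertension",
  "dyslipidemia",
  "hyperglycemia",
  "ms"
 ],
 "groups": {
  "male": {
   "n": [
    4730,
    5088,
    2678,
    1754
   ],
   "age_mean": [
    32.11,
    44.45,
    54.23,
    68.39
   ],
   "age_sd": [
    4.99,
    2.92,
    2.95,
    6.42
   ],
   "counts": {
    "overweight_obesity": [
     2220,
     2781,
     1513,
     933
    ],
    "hypertension": [
     981,
     1821,
     1241,
     1069
    ],
    "dyslipidemia": [
     1790,
     2554,
     1300,
     772
    ],
    "hyperglycemia": [
     193,
     627,
     582,
     501
    ],
    "ms": [
     489,
     1080,
     731,
     568
    ]
   }
  },
  "female": {
   "n": [
    3271,
    2705,
    892,
    659
   ],
   "age_mean": [
    31.45,
    44.32,
    53.46,
    66.92
   ],
   "age_sd": [
    5.14,
    2.88,
    2.85,
    5.22
   ],
   "counts": {
    "overweight_obesity": [
     418,
     484,
     295,
     320
    ],
    "hypertension": [
     193,
     338,
     241,
     383
    ],
    "dyslipidemia": [
     509,
     567,
     357,
     319
    ],
    "hyperglycemia": [
     72,
     92,
     81,
     149
    ],
    "ms": [
     63,
     82,
     96,
     180
    ]
   }
  }
 },
 "published_chisq": {
  "male": {
   "overweight_obesity": 85.382,
   "hypertension": 1096.064,
   "dyslipidemia": 167.648,
   "hyperglycemia": 869.355,
   "ms": 535.283
  },
  "female": {
   "overweight_obesity": 640.497,
   "hypertension": 1263.24,
   "dyslipidemia": 490.266,
   "hyperglycemia": 506.689,
   "ms": 750.878
  }
 },
 "notes": "Two published statistics are internally inconsistent with the published counts: male/hypertension (counts give 1077.778, not 1096.064) and female/overweight_obesity (counts give 542.050, not 640.497). The other eight reproduce exactly under an uncorrected Pearson test on the 2xk table. One published percentage is likewise inconsistent: male/hypertension in the 50-59 band prints 46.24% but 1241/2678 = 46.34%.",
 "published_pct": {
  "male": {
   "overweight_obesity": [
    46.93,
    54.66,
    56.5,
    53.19
   ],
   "hypertension": [
    20.74,
    35.79,
    46.24,
    60.95
   ],
   "dyslipidemia": [
    37.84,
    50.2,
    48.54,
    44.01
   ],
   "hyperglycemia": [
    4.08,
    12.32,
    21.73,
    28.56
   ],
   "ms": [
    10.34,
    21.23,
    27.3,
    32.38
   ]
  },
  "female": {
   "overweight_obesity": [
    12.78,
    17.89,
    33.07,
    48.56
   ],
   "hypertension": [
    5.9,
    12.5,
    27.02,
    58.12
   ],
   "dyslipidemia": [
    15.56,
    20.96,
    40.02,
    48.41
   ],
   "hyperglycemia": [
    2.2,
    3.4,
    9.08,
    22.61
   ],
   "ms": [
    1.93,
    3.03,
    10.76,
    27.31
   ]
  }
 }
}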