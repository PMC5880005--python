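# metsyn

A 12-state discrete-time Markov model of metabolic-syndrome (MS) progression,
built for epidemiologists analysing longitudinal health-check-up panels.

Under the Chinese Diabetes Society (CDS) criteria, MS is the co-occurrence of
at least three of four components — overweight/obesity (BMI ≥ 25.0 kg/m²),
hypertension (SBP ≥ 140 or DBP ≥ 90 mmHg, or anti-hypertensive use),
dyslipidemia (TG ≥ 1.7 mmol/L, or HDL-C < 0.9 mmol/L in men / < 1.0 in
women), and hyperglycemia (FPG ≥ 6.1 mmol/L, 2-h post-meal glucose ≥ 7.8
mmol/L, or anti-hyperglycemic use). The 16 component profiles collapse onto
12 mutually exclusive states: the no-component state, 4 isolated-component
states, 6 two-component states, and MS itself.

The model is a homogeneous annual-cycle Markov chain per stratum
(sex × {18–49, ≥ 50} at baseline age). With state occupancy π_t (a
12-vector) and annual transition matrix **P**,

&nbsp;&nbsp;&nbsp;&nbsp;π_t = π_{t−1} **P**,&nbsp;&nbsp; π_0 = e_s (point mass on the start state),

and **P** is estimated as the arithmetic mean of the five per-cycle observed
transition proportions p̂_ij^(c) = n_ij^(c) / n_i^(c) over a 6-year
check-up window (five one-year cycles), averaging each row over the cycles
in which it was observed. The MS "predictive rate" at year t is the MS
coordinate of π_t; an absorbing-MS variant (cumulative incidence of ever
entering MS) is always computed alongside.

The package provides:

- `metsyn.classify` — CDS component diagnosis and 12-state labelling of
  check-up tables (CSV in, augmented CSV out);
- `metsyn.cohort` — eligibility filtering (age 18–88, ≥ 2 consecutive annual
  visits, no CHD / type-I diabetes / familial hyperlipidemia, complete
  fields) with an exclusion report, stratification, and transition-pair
  extraction;
- `metsyn.transitions` — per-cycle tallies, cycle-averaged matrix
  estimation, and the four published reference matrices shipped as JSON
  fixtures;
- `metsyn.markov` — multi-year risk prediction, risk panels for all 12
  starting states, point-prevalence validation, and plotting;
- `metsyn.descriptives` — prevalence tables and uncorrected Pearson
  chi-square comparisons across age bands;
- `metsyn.simulate` — a synthetic cohort generator with known Markov
  dynamics, staggered 2010–2014 entry, geometric dropout, a
  measurement-rendering model with a classification round-trip guarantee,
  and an end-to-end parameter-recovery experiment.

## Worked example

Ten-year MS risk for women aged ≥ 50 who start with isolated dyslipidemia,
using the published reference matrix, followed by a parameter-recovery check
of the whole pipeline on a synthetic cohort:

```python
from metsyn import (load_printed_matrix, predict,
                    SyntheticCohortSpec, recovery_experiment)

m = load_printed_matrix("women_50plus")
traj = predict(m, "DYS", horizon=10)
for year in (1, 5, 10):
    print(f"year {year:2d}: P(MS) = {100*traj.ms_occupancy[year]:5.2f}%  "
          f"P(ever MS) = {100*traj.ms_cumulative[year]:5.2f}%")

report = recovery_experiment(SyntheticCohortSpec(n_subjects=5000, seed=0))
print({k: round(v, 3) for k, v in report.max_abs_err.items()})
```

```
year  1: P(MS) =  5.61%  P(ever MS) =  5.61%
year  5: P(MS) = 21.47%  P(ever MS) = 31.41%
year 10: P(MS) = 32.95%  P(ever MS) = 61.88%
{'women_18_49': 0.046, 'women_50plus': 0.036, 'men_18_49': 0.034, 'men_50plus': 0.035}
```

Year-1 risk is exactly the DYS→MS entry of the matrix (5.61%). Occupancy
(the probability of being in MS at year t, with exits allowed) grows to
32.95% by year 10, while the cumulative probability of ever having entered
MS reaches 61.88%. The recovery experiment simulates 5,000 subjects per
stratum from the known matrices, re-runs classification, filtering, pair
extraction and estimation, and reports the largest absolute error per
stratum — here ≤ 0.05, shrinking with cohort size (≤ 0.02 at 50,000 per
stratum).

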