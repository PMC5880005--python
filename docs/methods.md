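# Methods

## Model

Metabolic-syndrome progression is modelled as a first-order, time-homogeneous
discrete-time Markov chain on 12 states: NONE (no component), four
isolated-component states (OW, HTN, DYS, HYP), six two-component states
(OW_HTN, OW_DYS, OW_HYP, HTN_DYS, HTN_HYP, DYS_HYP), and MS (≥ 3
components). The cycle length is one calendar year. Two assumptions carry
the whole analysis: (1) the state next year depends only on the current
state (no history dependence, no covariates beyond the stratum), and (2) the
annual transition matrix is constant over the prediction horizon. Both are
strong; they are what make a 12 × 12 matrix a complete description of the
dynamics, and they are exactly what the synthetic-data generator implements,
so parameter-recovery tests validate the pipeline *under* these assumptions,
not the assumptions themselves.

States are classified from measurements by the CDS cut-offs. Boundary
behaviour follows each criterion's printed inequality: ≥ for BMI, SBP, DBP,
TG, FPG and 2-h glucose (a value exactly at the cut-off is positive), strict
< for the sex-specific HDL cut-offs (a value exactly at the cut-off is
negative). Medication flags substitute only for their own component.
2-h post-meal glucose is optional; when absent, hyperglycemia is decided
from FPG and medication alone. When height and weight are both present, BMI
is recomputed as weight/height² and overrides a supplied BMI that disagrees
by more than 0.1 kg/m² (logged).

## Estimation

Within each stratum (sex × baseline-age band 18–49 / ≥ 50; the stratum is
fixed at baseline and never updated, since the source design stratifies
subjects, not person-years), every adjacent same-subject visit pair exactly
one year apart contributes one transition. Pairs are indexed into cycles by
from-visit year (cycle = year − start_year + 1; a 2010–2015 window gives
cycles 1..5). Each cycle yields a proportion matrix; rows with zero at-risk
denominator are *undefined* (NaN), not zero — averaging them as zeros would
bias every probability toward 0 and break row-stochasticity. The model
matrix is the per-row arithmetic mean over defined cycles, renormalised to
sum to 1 (the pre-normalisation deviation is logged). A row observed in no
cycle is completed as the identity row (self-retention 1) and loudly
flagged: self-retention is the least-assumptive completion that keeps the
matrix usable for prediction.

The four published reference matrices ship as JSON fixtures in percent with
per-row checksums; loading validates every row sum to 100 ± 0.05 before
converting to proportions and renormalising. One cell of the men-18–49
isolated-hyperglycemia row is typographically corrupt in its source
("0.6.24"); the fixture resolves it as 6.24% in the OW_HYP column because
the row then sums to 99.99 and the analogous cell is nonzero in the other
strata. The row-sum argument cannot distinguish the OW_HYP and OW_DYS
placements, so `load_printed_matrix(..., alternate_corrupt_cell=True)`
provides the alternative.

## Prediction and validation

Year 0 is a point mass on the starting state; occupancy propagates by
π_t = π_{t−1}P. The headline "predictive rate" of MS is the MS coordinate
of π_t under the full reversible matrix — the published matrices contain
exits from MS, and point-prevalence validation compares against occupancy.
The absorbing-MS cumulative incidence (P row for MS replaced by the identity
row) is always computed alongside; it is monotone, dominates occupancy, and
tends to 1 whenever MS is reachable from everywhere. The occupancy semantics
was confirmed empirically: five cycles from NONE give 18.10% (men 18–49) and
5.14% (women 18–49) against published model estimates of 18.22% and 5.33%,
whereas the absorbing variant gives 24.27% and 8.38%. The residual 0.12/0.19
percentage points is consistent with propagating matrices rounded to
2-decimal percent: with up to 12 entries per row each perturbed by ≤ 0.005
points, five steps can move a coordinate by roughly 0.3 points, which is the
comparison tolerance used in the acceptance tests.

Cohort validation (`markov.validate`) compares predicted occupancy at year t
with the fraction of subjects in MS exactly t years after baseline among
those who started in the given state, reporting both with denominators and
flagging empty cells rather than failing.

## Descriptives

Prevalence tables report count and percentage (2 decimals) per cell, at
baseline by sex × fine age band (18–39/40–49/50–59/≥ 60) or by follow-up
year. Categorical comparisons use the uncorrected Pearson chi-square on the
2 × k table (df = k − 1), via `scipy.stats.chi2_contingency`; the test
suite cross-checks it against a direct Σ(O−E)²/E summation. p-values below
1e-4 are formatted "< 0.0001". The published baseline and follow-up counts
are shipped as fixtures; recomputing their percentages and statistics
reproduces the published values in all but seven cells (two chi-square
statistics and five percentages) that are internally inconsistent with
their own printed counts — the fixture `notes` fields document each one,
and the acceptance tests deliberately leave those comparisons failing
rather than encode the inconsistent numbers.

One published ordering claim fails under the published matrices themselves:
for men 18–49, the 10-year MS risk starting from DYS_HYP (41.8%) is below
that from OW_HTN (42.3%), under occupancy and cumulative semantics alike,
so "every hyperglycemia-containing pair start exceeds every other pair
start" holds in three strata of four. The corresponding acceptance check is
kept faithful and fails for that stratum.

## Synthetic cohorts

The generator emulates the panel structure the estimator assumes: entry
uniform over 2010–2014; visits annual and consecutive, with a minimum of 2
and a geometric continuation thereafter (default per-year dropout 0.25,
chosen to approximate the roughly halving visit counts over follow-up in
the source cohort), capped at 2015; default stratum sizes match the
published cohort composition (men 18–49: 9,818; women 18–49: 5,976; men
≥ 50: 4,432; women ≥ 50: 1,551); state sequences are independent
realisations of the stratum's chain from a configurable initial
distribution (default uniform over the 12 states, which exercises every
matrix row — real cohorts are far more concentrated).

Measurements are rendered from truncated uniform distributions on the
correct side of each cut-off, with a configurable exclusion margin (default
0, so boundary values occur — boundary behaviour is where classification
bugs live) and rounding to realistic precision (BMI 0.1, BP 1 mmHg, lipids
and glucose 0.01), with ranges chosen so rounding can never cross a
cut-off. Hypertension and hyperglycemia are realised through medication
flags with configurable probability (default 0.3) and otherwise through
elevated values; MS rows draw one of the five ≥ 3-component profiles
uniformly. This yields the round-trip guarantee — every rendered row
classifies back to exactly its generating state — which is tested property
style. Deliberately ineligible subjects (disease flags, missing fields,
out-of-range ages) can be planted at configurable rates; the eligibility
filter must remove exactly them.

What the generator does *not* emulate: within-state correlation among
measurements (a subject's BMI is redrawn each year), informative dropout,
covariate effects, or real marginal distributions of the biomarkers.
Passing recovery tests therefore demonstrates correctness of the pipeline's
accounting — classification, filtering, pairing, tallying, averaging — not
robustness to violations of the Markov assumptions.

## Numerical choices and problem sizes

Row-stochasticity is enforced at 1e-9; propagation oracles
(Chapman–Kolmogorov vs matrix power) agree at 1e-9; fixture row sums at
±0.05 percent. The recovery experiment in the acceptance suite uses 50,000
subjects per stratum (maximum per-entry error observed ≈ 0.017, against a
0.02 binomial-error bound at the realised denominators); unit tests use
2,000–20,000 to keep the suite fast while still demonstrating the
error-shrinks-with-n consistency property. Pseudo-randomness flows from a
single `numpy` Generator seeded per spec; identical specs produce
byte-identical CSV output.

## Limitations

Homogeneous transition probabilities over a 10-year horizon ignore ageing
across the 50-year boundary, secular trends, and treatment effects; the
four post-MS 3-component states are not distinguished (MS is a single
state, entered at ≥ 3 components); transition probabilities carry no
uncertainty intervals; and the strict-inequality HDL cut-off makes
classification sensitive to reported precision at exactly 0.9/1.0 mmol/L.
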