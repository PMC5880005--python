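"""Synthetic longitudinal check-up cohorts with known Markov dynamics.

The generator emulates the structure the analysis assumes: staggered cohort
entry across five calendar years, consecutive annual visits with geometric
dropout, per-stratum 12-state Markov state dynamics, and clinical
measurements drawn so that each rendered row classifies back (through the
CDS classifier) to exactly its generating state.  Because the true
transition matrices are known, the full pipeline can be checked by parameter
recovery: simulate, render, classify, extract pairs, estimate, and compare
to the truth.

Default cohort sizes match the four published stratum sizes (men 18-49:
9,818; women 18-49: 5,976; men 50+: 4,432; women 50+: 1,551), entry is
uniform over 2010-2014, and the default matrices are the published fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import CUTOFFS, classify_table
from .cohort import Stratum, add_strata, apply_eligibility, extract_pairs
from .states import STATE_ORDER, InputError, MetabolicState, Sex, profile_of_state
from .transitions import (N_STATES, TransitionMatrix, estimate_matrices,
                          load_all_printed_matrices)

__all__ = [
    "MeasurementModel",
    "SyntheticCohortSpec",
    "GeneratedCohort",
    "RecoveryReport",
    "simulate_states",
    "render_measurements",
    "generate_cohort",
    "recovery_experiment",
]

_LABELS = [s.value for s in STATE_ORDER]

#: Published stratum sizes used as the default cohort composition.
DEFAULT_N = {
    "men_18_49": 9818,
    "women_18_49": 5976,
    "men_50plus": 4432,
    "women_50plus": 1551,
}

# sampling ranges (lo, hi) on the negative / positive side of each cut-off,
# chosen so that values rounded to the stated precision still classify
# correctly: bmi 1 dp, blood pressure integer mmHg, lipids/glucose 2 dp
_BMI_NEG, _BMI_POS = (18.0, 24.9), (25.0, 33.0)
_SBP_NEG, _SBP_POS = (95, 139), (140, 180)
_DBP_NEG = (55, 89)
_TG_NEG, _TG_POS = (0.50, 1.69), (1.70, 4.00)
_HDL_POS_SPAN = 1.2        # healthy HDL: [cut, cut + span]
_HDL_NEG_LO = 0.40         # low HDL: [0.40, cut - 0.01]
_FPG_NEG, _FPG_POS = (3.90, 6.09), (6.10, 9.00)
_PG2H_NEG, _PG2H_POS = (4.00, 7.79), (7.80, 13.00)


@dataclass(frozen=True)
class MeasurementModel:
    """Conditional measurement-sampling rules given the component flags.

    ``margin`` widens the exclusion zone around every cut-off (default 0:
    boundary values are allowed, so threshold code paths get exercised).
    Medication flags are used as the positive mechanism for hypertension /
    hyperglycemia with the configured probabilities; ``pg2h_rate`` is the
    fraction of rows carrying a 2-h post-meal glucose value (it is rarely
    measured at routine check-ups).
    """

    margin: float = 0.0
    med_prob_hypertension: float = 0.3
    med_prob_hyperglycemia: float = 0.3
    tg_mechanism_prob: float = 0.6   # positive dyslipidemia via high TG (else low HDL)
    pg2h_rate: float = 0.1


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full parameterisation of the simulator; the seed determines the output.

    ``n_subjects`` may be a single int (applied to every stratum) or a dict
    keyed by stratum; ``matrices`` defaults to the published fixtures and
    ``initial_distribution`` to uniform over the 12 states.  ``dropout_prob``
    is the per-year probability of leaving after the ``min_visits``-th visit;
    visits are capped by the ``end_year`` window.  ``contamination`` maps
    planting reasons (``disease``, ``missing``, ``age``) to subject fractions.
    """

    n_subjects: int | dict[str, int] | None = None
    start_year: int = 2010
    end_year: int = 2015
    entry_year_probs: dict[int, float] | None = None  # default uniform 2010-2014
    min_visits: int = 2
    dropout_prob: float = 0.25
    matrices: dict[str, TransitionMatrix] | None = None
    initial_distribution: dict[str, np.ndarray] | None = None
    measurement_model: MeasurementModel = field(default_factory=MeasurementModel)
    contamination: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def resolved_n(self) -> dict[str, int]:
        if self.n_subjects is None:
            return dict(DEFAULT_N)
        if isinstance(self.n_subjects, int):
            return {k: self.n_subjects for k in DEFAULT_N}
        return dict(self.n_subjects)

    def resolved_matrices(self) -> dict[str, TransitionMatrix]:
        mats = self.matrices or load_all_printed_matrices()
        for m in mats.values():
            m.validate()
        return mats

    def resolved_initial(self, stratum: str) -> np.ndarray:
        if self.initial_distribution and stratum in self.initial_distribution:
            p = np.asarray(self.initial_distribution[stratum], dtype=float)
            if p.shape != (N_STATES,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
                raise InputError(f"initial distribution for {stratum} is not proper")
            return p
        return np.full(N_STATES, 1.0 / N_STATES)

    def resolved_entry_probs(self) -> tuple[np.ndarray, np.ndarray]:
        if self.entry_year_probs is None:
            years = np.arange(self.start_year, self.end_year)
            return years, np.full(len(years), 1.0 / len(years))
        years = np.array(sorted(self.entry_year_probs))
        p = np.array([self.entry_year_probs[y] for y in years], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
            raise InputError("entry-year distribution is not proper")
        return years, p


@dataclass
class GeneratedCohort:
    """Simulator output: check-up records, the planted per-visit states, and
    the ids of contaminated (deliberately ineligible) subjects by reason."""

    records: pd.DataFrame
    states: pd.DataFrame
    contaminated: dict[str, list[str]]
    spec: SyntheticCohortSpec


def _markov_paths(P: np.ndarray, init: np.ndarray, n_visits: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample state paths; returns (n, max_visits) int array, -1 past dropout."""
    n = len(n_visits)
    max_v = int(n_visits.max())
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    paths = np.full((n, max_v), -1, dtype=np.int8)
    cur = rng.choice(N_STATES, size=n, p=init)
    paths[:, 0] = cur
    for t in range(1, max_v):
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int8)
        for s in range(N_STATES):
            m = cur == s
            if m.any():
                nxt[m] = np.searchsorted(cum[s], u[m], side="right")
        cur = nxt
        alive = n_visits > t
        paths[alive, t] = cur[alive]
    return paths


def simulate_states(spec: SyntheticCohortSpec,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Realise each subject's annual state sequence from its stratum's chain.

    Returns one row per subject-visit: ``subject_id``, ``sex``, ``age_band``,
    ``stratum``, ``entry_year``, ``visit_year``, ``year_index``, ``state``,
    ``baseline_age``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    mats = spec.resolved_matrices()
    entry_years, entry_p = spec.resolved_entry_probs()
    frames = []
    for key, n in sorted(spec.resolved_n().items()):
        if n <= 0:
            continue
        stratum = Stratum.from_key(key)
        P = mats[key].probs
        entry = rng.choice(entry_years, size=n, p=entry_p)
        cap = spec.end_year - entry + 1
        extra = rng.geometric(spec.dropout_prob, size=n) - 1
        n_visits = np.minimum(spec.min_visits + extra, cap)
        lo, hi = (18, 49) if stratum.age_band == "18-49" else (50, 80)
        base_age = rng.integers(lo, hi + 1, size=n)

        paths = _markov_paths(P, spec.resolved_initial(key), n_visits, rng)
        sid = np.array([f"{key}_{i:06d}" for i in range(n)])
        v = n_visits.astype(int)
        rep = np.repeat(np.arange(n), v)
        year_index = np.concatenate([np.arange(k) for k in v])
        frames.append(pd.DataFrame({
            "subject_id": sid[rep],
            "sex": stratum.sex.value,
            "age_band": stratum.age_band,
            "stratum": key,
            "entry_year": entry[rep],
            "visit_year": entry[rep] + year_index,
            "year_index": year_index,
            "state": np.array(_LABELS)[paths[rep, year_index]],
            "baseline_age": base_age[rep],
        }))
    if not frames:
        raise InputError("spec yields no subjects")
    return pd.concat(frames, ignore_index=True)


def _uniform_round(rng, lo, hi, size, decimals):
    return np.round(rng.uniform(lo, hi, size), decimals)


def render_measurements(states: pd.DataFrame,
                        model: MeasurementModel | None = None,
                        rng: np.random.Generator | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Render clinical measurements consistent with each row's state.

    Every rendered row classifies back, via the CDS classifier, to exactly
    its generating state (the round-trip guarantee).  For MS rows the
    component profile is drawn uniformly from the five >= 3-component
    profiles.
    """
    model = model or MeasurementModel()
    rng = rng or np.random.default_rng(seed)
    n = len(states)
    m = model.margin

    state_idx = states["state"].map(
        {lab: i for i, lab in enumerate(_LABELS)}).to_numpy()
    # profile lookup: for non-MS states one profile; MS rows sample one of 5
    flags = np.zeros((n, 4), dtype=bool)
    for i, s in enumerate(STATE_ORDER):
        mask = state_idx == i
        if not mask.any():
            continue
        profiles = profile_of_state(s)
        if len(profiles) == 1:
            flags[mask] = profiles[0].flags
        else:
            pick = rng.integers(0, len(profiles), size=int(mask.sum()))
            table = np.array([p.flags for p in profiles], dtype=bool)
            flags[mask] = table[pick]
    ow, htn, dys, hyp = flags.T
    male = (states["sex"] == Sex.MALE.value).to_numpy()

    out = states[["subject_id", "visit_year"]].copy()
    out["age"] = (states["baseline_age"] + states["year_index"]).to_numpy()
    out["sex"] = states["sex"].to_numpy()

    # overweight/obesity: BMI on the required side of 25.0
    bmi = _uniform_round(rng, _BMI_NEG[0], _BMI_NEG[1] - m, n, 1)
    bmi[ow] = _uniform_round(rng, _BMI_POS[0] + m, _BMI_POS[1], int(ow.sum()), 1)
    out["bmi"] = bmi

    # hypertension: medication with stated probability, else elevated BP
    med_htn = htn & (rng.random(n) < model.med_prob_hypertension)
    high_bp = htn & ~med_htn
    sbp = rng.integers(*_SBP_NEG, size=n, endpoint=True)
    dbp = np.minimum(rng.integers(*_DBP_NEG, size=n, endpoint=True), sbp - 10)
    k = int(high_bp.sum())
    sbp[high_bp] = rng.integers(_SBP_POS[0] + int(np.ceil(m)), _SBP_POS[1],
                                size=k, endpoint=True)
    dbp[high_bp] = rng.integers(85, 105, size=k, endpoint=True)
    out["sbp"], out["dbp"] = sbp, dbp
    out["on_antihypertensive"] = med_htn

    # dyslipidemia: high TG or low HDL (or both); sex-specific HDL cut-off
    hdl_cut = np.where(male, CUTOFFS["hdl_male"], CUTOFFS["hdl_female"])
    tg = _uniform_round(rng, _TG_NEG[0], _TG_NEG[1] - m, n, 2)
    hdl = np.round(rng.uniform(hdl_cut + m, hdl_cut + _HDL_POS_SPAN), 2)
    via_tg = dys & (rng.random(n) < model.tg_mechanism_prob)
    via_hdl = dys & ~via_tg
    tg[via_tg] = _uniform_round(rng, _TG_POS[0] + m, _TG_POS[1], int(via_tg.sum()), 2)
    low = np.round(rng.uniform(_HDL_NEG_LO, hdl_cut - 0.01 - m), 2)
    hdl[via_hdl] = low[via_hdl]
    out["tg"], out["hdl"] = tg, hdl

    # hyperglycemia: medication, else high FPG; pg2h rarely present
    med_hyp = hyp & (rng.random(n) < model.med_prob_hyperglycemia)
    high_fpg = hyp & ~med_hyp
    fpg = _uniform_round(rng, _FPG_NEG[0], _FPG_NEG[1] - m, n, 2)
    fpg[high_fpg] = _uniform_round(rng, _FPG_POS[0] + m, _FPG_POS[1],
                                   int(high_fpg.sum()), 2)
    pg2h = np.full(n, np.nan)
    has_pg = rng.random(n) < model.pg2h_rate
    pg_neg = has_pg & ~hyp
    pg2h[pg_neg] = _uniform_round(rng, _PG2H_NEG[0], _PG2H_NEG[1] - m,
                                  int(pg_neg.sum()), 2)
    pg_pos = has_pg & hyp
    pg2h[pg_pos] = _uniform_round(rng, _PG2H_POS[0] + m, _PG2H_POS[1],
                                  int(pg_pos.sum()), 2)
    out["fpg"], out["pg2h"] = fpg, pg2h
    out["on_antihyperglycemic"] = med_hyp

    out["has_chd"] = False
    out["has_t1dm"] = False
    out["has_familial_hyperlipidemia"] = False
    return out


def generate_cohort(spec: SyntheticCohortSpec) -> GeneratedCohort:
    """Simulate states, render measurements, and plant contaminated subjects.

    Contamination reasons: ``disease`` sets one of the CHD / type-I-diabetes /
    familial-hyperlipidemia flags on one visit; ``missing`` blanks one
    required measurement on one visit; ``age`` pushes the baseline age
    outside 18-88.  Contaminated subject sets are disjoint, so the
    eligibility filter should remove exactly their union.
    """
    rng = np.random.default_rng(spec.seed)
    states = simulate_states(spec, rng)
    records = render_measurements(states, spec.measurement_model, rng)

    contaminated: dict[str, list[str]] = {}
    if spec.contamination:
        subjects = states["subject_id"].unique()
        rng.shuffle(subjects)
        pos = 0
        for reason in ("disease", "missing", "age"):
            frac = spec.contamination.get(reason, 0.0)
            k = int(round(frac * len(subjects)))
            chosen = subjects[pos:pos + k]
            pos += k
            contaminated[reason] = list(chosen)
            mask = records["subject_id"].isin(chosen)
            idx = records.index[mask]
            if reason == "disease":
                first = records.loc[idx].groupby(records.loc[idx, "subject_id"]).head(1).index
                col = rng.choice(["has_chd", "has_t1dm",
                                  "has_familial_hyperlipidemia"], size=len(first))
                for c in ("has_chd", "has_t1dm", "has_familial_hyperlipidemia"):
                    records.loc[first[col == c], c] = True
            elif reason == "missing":
                first = records.loc[idx].groupby(records.loc[idx, "subject_id"]).head(1).index
                col = rng.choice(["bmi", "sbp", "tg", "hdl", "fpg"], size=len(first))
                for c in ("bmi", "sbp", "tg", "hdl", "fpg"):
                    records.loc[first[col == c], c] = np.nan
            else:  # age: move the whole trajectory to a baseline outside 18-88
                target = dict(zip(chosen, rng.choice([10.0, 95.0], size=len(chosen))))
                sub = records.loc[idx]
                first_age = sub.groupby("subject_id")["age"].transform("min")
                offset = sub["subject_id"].map(target) - first_age
                records.loc[idx, "age"] = sub["age"] + offset
    return GeneratedCohort(records=records, states=states,
                           contaminated=contaminated, spec=spec)


@dataclass
class RecoveryReport:
    """Per-stratum agreement between estimated and generating matrices,
    restricted to rows that were actually observed (not identity-filled)."""

    max_abs_err: dict[str, float]
    rms_err: dict[str, float]
    n_pairs: dict[str, int]
    filled_rows: dict[str, tuple[MetabolicState, ...]]
    estimates: dict[str, TransitionMatrix]

    @property
    def overall_max_abs_err(self) -> float:
        return max(self.max_abs_err.values())


def run_pipeline(records: pd.DataFrame, start_year: int = 2010,
                 end_year: int = 2015):
    """Classify, filter, stratify and estimate: the full analysis pipeline.

    Returns ``(matrices, pairs, cohort, exclusion_report)``.
    """
    classified = classify_table(records)
    eligible, report = apply_eligibility(classified, start_year, end_year)
    cohort = add_strata(eligible)
    pairs = extract_pairs(cohort, start_year)
    return estimate_matrices(pairs), pairs, cohort, report


def recovery_experiment(spec: SyntheticCohortSpec) -> RecoveryReport:
    """Generate a cohort from known matrices and re-estimate them end to end.

    Error metrics compare estimated and true entries over rows observed in at
    least one cycle; identity-filled rows are reported separately.
    """
    gen = generate_cohort(spec)
    mats, pairs, _, _ = run_pipeline(gen.records, spec.start_year, spec.end_year)
    truth = spec.resolved_matrices()

    pair_key = (np.where(pairs["sex"] == Sex.MALE.value, "men", "women")
                + np.where(pairs["age_band"] == "18-49", "_18_49", "_50plus"))
    pair_counts = pd.Series(pair_key).value_counts()

    max_err, rms, npairs, filled = {}, {}, {}, {}
    for key, est in mats.items():
        diff = est.probs - truth[key].probs
        keep = np.ones(N_STATES, dtype=bool)
        for s in est.filled_rows:
            keep[s.index] = False
        d = diff[keep]
        max_err[key] = float(np.abs(d).max())
        rms[key] = float(np.sqrt(np.mean(d**2)))
        npairs[key] = int(pair_counts.get(key, 0))
        filled[key] = est.filled_rows
    return RecoveryReport(max_abs_err=max_err, rms_err=rms, n_pairs=npairs,
                          filled_rows=filled, estimates=mats)


def small_spec(n: int = 500, seed: int = 0, **kwargs) -> SyntheticCohortSpec:
    """Convenience spec with n subjects per stratum (tests, examples)."""
    return SyntheticCohortSpec(n_subjects=n, seed=seed, **kwargs)
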