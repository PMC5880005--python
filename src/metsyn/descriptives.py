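"""Descriptive layer: prevalence tables and chi-square comparisons.

Prevalence is reported as count and percentage per cell, either at baseline
stratified by sex and fine age band (18-39 / 40-49 / 50-59 / 60+) or by
follow-up year.  Group differences in categorical outcomes use the
uncorrected Pearson chi-square test on the 2 x k positive/negative table,
df = k - 1.  p-values below 1e-4 are formatted as "< 0.0001".

The published counts that the package reproduces its descriptive statistics
from are shipped as JSON fixtures (see :func:`load_baseline_counts` and
:func:`load_followup_counts`).
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .states import COMPONENT_FIELDS, InputError, MetabolicState

__all__ = [
    "prevalence",
    "chisq_across_groups",
    "format_p",
    "format_pct",
    "load_baseline_counts",
    "load_followup_counts",
    "baseline_table",
]

OUTCOMES = (*COMPONENT_FIELDS, "ms")


def chisq_across_groups(positives, totals) -> tuple[float, int, float]:
    """Pearson chi-square comparing a proportion across k groups.

    Parameters are the k positive counts and the k group totals.  The test is
    run on the 2 x k contingency table (positive / negative by group) without
    continuity correction; df = k - 1.

    Raises an explicit error (never a silent NaN) when k < 2, a denominator
    is non-positive, or an expected cell count is zero.
    """
    pos = np.asarray(positives, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if pos.shape != tot.shape or pos.ndim != 1 or pos.size < 2:
        raise InputError("need k >= 2 matching positive counts and totals")
    if np.any(tot <= 0):
        raise InputError("all group denominators must be positive")
    if np.any(pos < 0) or np.any(pos > tot):
        raise InputError("positive counts must lie in [0, total] per group")
    table = np.vstack([pos, tot - pos])
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise InputError("zero expected cell count; chi-square undefined")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def format_p(p: float, threshold: float = 1e-4) -> str:
    """Render a p-value, collapsing tiny values to "< 0.0001"."""
    return "< 0.0001" if p < threshold else f"{p:.4f}"


def format_pct(count: int, denom: int) -> str:
    return f"{100.0 * count / denom:.2f}%"


def _outcome_columns(df: pd.DataFrame) -> dict[str, pd.Series]:
    cols = {}
    for c in COMPONENT_FIELDS:
        if c not in df.columns:
            raise InputError(f"cohort lacks component column {c!r}; classify first")
        cols[c] = df[c].astype(bool)
    cols["ms"] = df["state"] == MetabolicState.MS.value
    return cols


def prevalence(cohort: pd.DataFrame, grouping: str = "baseline") -> pd.DataFrame:
    """Counts and percentages of the four components and MS, per group.

    ``grouping="baseline"`` uses each subject's first visit, grouped by sex
    and fine age band (requires the columns added by
    :func:`metsyn.cohort.add_strata`); ``grouping="followup_year"`` uses every
    visit, grouped by years since baseline.  Empty groups are flagged rather
    than dropped.  Percentages are reported to 2 decimals.
    """
    df = cohort.sort_values(["subject_id", "visit_year"], kind="mergesort")
    if grouping == "baseline":
        df = df.groupby("subject_id", as_index=False).first()
        keys = ["sex", "fine_band"]
    elif grouping == "followup_year":
        df = df.copy()
        base = df.groupby("subject_id")["visit_year"].transform("first")
        df["followup_year"] = (df["visit_year"] - base).astype(int)
        keys = ["followup_year"]
    else:
        raise InputError(f"unknown grouping {grouping!r}")

    outcomes = _outcome_columns(df)
    rows = []
    for key_vals, sub in df.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        denom = len(sub)
        for name, col in outcomes.items():
            count = int(col.loc[sub.index].sum())
            rows.append({
                **dict(zip(keys, key_vals)),
                "outcome": name,
                "count": count,
                "denominator": denom,
                "percent": round(100.0 * count / denom, 2) if denom else np.nan,
                "empty": denom == 0,
            })
    return pd.DataFrame(rows)


def _load_data(name: str) -> dict:
    ref = resources.files("metsyn.data").joinpath(name)
    return json.loads(ref.read_text())


def load_baseline_counts() -> dict:
    """Published baseline counts by sex and fine age band, with the published
    chi-square statistics comparing the four age bands within each sex."""
    return _load_data("baseline_characteristics.json")


def load_followup_counts() -> dict:
    """Published per-follow-up-year visit and outcome counts."""
    return _load_data("followup_cohort.json")


def baseline_table(counts: dict | None = None) -> pd.DataFrame:
    """Rebuild the baseline descriptive table (counts, percentages, recomputed
    chi-square and formatted p) from a counts payload; defaults to the
    published counts fixture.  Age mean +/- SD rows are carried through
    verbatim (they are inputs, not recomputable from counts)."""
    payload = counts or load_baseline_counts()
    bands = payload["age_bands"]
    rows = []
    for sex, grp in payload["groups"].items():
        n = grp["n"]
        rows.append({"sex": sex, "variable": "N",
                     **{b: str(v) for b, v in zip(bands, n)}})
        rows.append({"sex": sex, "variable": "age",
                     **{b: f"{m:.2f} ± {s:.2f}"
                        for b, m, s in zip(bands, grp["age_mean"], grp["age_sd"])}})
        for outcome, pos in grp["counts"].items():
            stat, dof, p = chisq_across_groups(pos, n)
            rows.append({
                "sex": sex, "variable": outcome,
                **{b: f"{c} ({format_pct(c, d)})"
                   for b, c, d in zip(bands, pos, n)},
                "chisq": round(stat, 3), "df": dof, "p": format_p(p),
            })
    return pd.DataFrame(rows)
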