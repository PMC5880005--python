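"""Cohort construction: eligibility filtering, stratification, transition pairs.

Eligibility mirrors a 6-year check-up cohort design: baseline age 18-88, at
least two visits in consecutive calendar years, no coronary heart disease,
type I diabetes or familial hyperlipidemia, and complete required fields at
every visit.  Each subject's first visit year is the baseline; strata are
fixed at baseline (sex x age band) and never updated during follow-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .states import InputError, MetabolicState, Sex

__all__ = [
    "Stratum",
    "MODEL_STRATA",
    "ExclusionReport",
    "EmptyCohortError",
    "EligibilityError",
    "apply_eligibility",
    "assign_stratum",
    "fine_age_band",
    "model_age_band",
    "add_strata",
    "extract_pairs",
]

MODEL_AGE_BANDS = ("18-49", "50+")
FINE_AGE_BANDS = ("18-39", "40-49", "50-59", "60+")

_REQUIRED = ["subject_id", "visit_year", "age", "sex",
             "bmi", "sbp", "dbp", "tg", "hdl", "fpg"]


class EmptyCohortError(ValueError):
    """Raised when eligibility filtering is asked to run on no records."""


class EligibilityError(ValueError):
    """Raised when an operation meets a record that should have been filtered."""


@dataclass(frozen=True)
class Stratum:
    """A modelling stratum: sex crossed with the coarse age band."""

    sex: Sex
    age_band: str  # "18-49" or "50+"

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if self.age_band not in MODEL_AGE_BANDS:
            raise InputError(f"unknown age band: {self.age_band!r}")

    @property
    def key(self) -> str:
        """Canonical fixture key, e.g. ``men_18_49`` or ``women_50plus``."""
        sex = "men" if self.sex is Sex.MALE else "women"
        band = "18_49" if self.age_band == "18-49" else "50plus"
        return f"{sex}_{band}"

    @classmethod
    def from_key(cls, key: str) -> "Stratum":
        sex_part, _, band_part = key.partition("_")
        sex = Sex.MALE if sex_part == "men" else Sex.FEMALE
        band = "18-49" if band_part == "18_49" else "50+"
        return cls(sex, band)


MODEL_STRATA = tuple(
    Stratum(sex, band) for sex in Sex for band in MODEL_AGE_BANDS
)


def fine_age_band(age: float) -> str:
    """Four-band descriptive grouping from baseline age."""
    if not 18 <= age <= 88:
        raise EligibilityError(f"baseline age {age} outside 18-88")
    if age < 40:
        return "18-39"
    if age < 50:
        return "40-49"
    if age < 60:
        return "50-59"
    return "60+"


def model_age_band(age: float) -> str:
    """Two-band modelling grouping from baseline age."""
    if not 18 <= age <= 88:
        raise EligibilityError(f"baseline age {age} outside 18-88")
    return "18-49" if age < 50 else "50+"


def assign_stratum(sex: Sex | str, baseline_age: float) -> Stratum:
    """Modelling stratum from sex and baseline age (fixed for all follow-up)."""
    return Stratum(Sex.parse(sex), model_age_band(baseline_age))


@dataclass
class ExclusionReport:
    """Counts and subject ids of exclusions, by first triggering reason.

    Reasons partition the excluded set; the priority order is
    age -> disease history -> missing/invalid fields -> no consecutive visits.
    """

    counts: dict[str, int] = field(default_factory=dict)
    subjects: dict[str, list] = field(default_factory=dict)

    REASONS = (
        "age_out_of_range",
        "disease_history",
        "missing_or_invalid_fields",
        "no_consecutive_visits",
    )

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def add(self, reason: str, subject_id) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1
        self.subjects.setdefault(reason, []).append(subject_id)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"n_excluded": self.n_excluded, "counts": self.counts,
             "subjects": {k: list(map(str, v)) for k, v in self.subjects.items()}},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _has_consecutive_pair(years) -> bool:
    ys = sorted(set(int(y) for y in years))
    return any(b - a == 1 for a, b in zip(ys, ys[1:]))


def apply_eligibility(
    records: pd.DataFrame,
    start_year: int = 2010,
    end_year: int = 2015,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Filter a check-up table down to the eligible cohort.

    A subject is retained when the baseline (first-visit) age is in [18, 88],
    no visit carries a CHD / type-I-diabetes / familial-hyperlipidemia flag,
    every visit has complete, physiologically valid required fields
    (sbp > dbp > 0, bmi > 0, tg/hdl/fpg >= 0), and at least one pair of
    visits falls in consecutive calendar years.  Each excluded subject is
    counted once, under the first reason in the documented priority order.

    Returns the retained rows (sorted by subject and year, restricted to
    ``start_year``..``end_year``) and the :class:`ExclusionReport`.
    """
    if records is None or len(records) == 0:
        raise EmptyCohortError("no input records")
    missing_cols = [c for c in _REQUIRED if c not in records.columns]
    if missing_cols:
        raise InputError(f"input table lacks required columns: {missing_cols}")

    df = records.copy()
    df = df[(df["visit_year"] >= start_year) & (df["visit_year"] <= end_year)]
    if len(df) == 0:
        raise EmptyCohortError(
            f"no records within the {start_year}-{end_year} window"
        )
    df = df.sort_values(["subject_id", "visit_year"], kind="mergesort")

    num = {c: pd.to_numeric(df[c], errors="coerce")
           for c in ("bmi", "sbp", "dbp", "tg", "hdl", "fpg")}
    row_missing = df[_REQUIRED].isna().any(axis=1)
    row_invalid = (
        ~(num["bmi"] > 0)
        | ~(num["sbp"] > num["dbp"])
        | ~(num["dbp"] > 0)
        | (num["tg"] < 0) | (num["hdl"] < 0) | (num["fpg"] < 0)
    )
    bad_row = (row_missing | row_invalid).groupby(df["subject_id"]).any()

    def disease_flag(col):
        if col not in df.columns:
            return pd.Series(False, index=df.index)
        return df[col].fillna(False).astype(bool)

    diseased = (
        disease_flag("has_chd")
        | disease_flag("has_t1dm")
        | disease_flag("has_familial_hyperlipidemia")
    ).groupby(df["subject_id"]).any()

    baseline_age = df.groupby("subject_id")["age"].first()
    age_bad = ~baseline_age.between(18, 88) | baseline_age.isna()
    consecutive = df.groupby("subject_id")["visit_year"].agg(_has_consecutive_pair)

    report = ExclusionReport()
    excluded = set()
    for reason, mask in [
        ("age_out_of_range", age_bad),
        ("disease_history", diseased),
        ("missing_or_invalid_fields", bad_row),
        ("no_consecutive_visits", ~consecutive),
    ]:
        for sid in mask[mask].index:
            if sid not in excluded:
                excluded.add(sid)
                report.add(reason, sid)

    eligible = df[~df["subject_id"].isin(excluded)].reset_index(drop=True)
    return eligible, report


def add_strata(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach baseline-derived columns: ``baseline_year``, ``baseline_age``,
    ``age_band`` (modelling) and ``fine_band`` (descriptive).  Input rows must
    already be eligibility-filtered and sorted by subject/visit year."""
    out = cohort.sort_values(["subject_id", "visit_year"], kind="mergesort").copy()
    grp = out.groupby("subject_id")
    out["baseline_year"] = grp["visit_year"].transform("first")
    out["baseline_age"] = grp["age"].transform("first")
    if (~out["baseline_age"].between(18, 88)).any():
        raise EligibilityError("baseline age outside 18-88 after filtering")
    out["age_band"] = out["baseline_age"].map(model_age_band)
    out["fine_band"] = out["baseline_age"].map(fine_age_band)
    return out


def extract_pairs(cohort: pd.DataFrame, start_year: int = 2010) -> pd.DataFrame:
    """Extract one transition pair per adjacent same-subject visit pair that is
    exactly one calendar year apart.

    ``cycle`` = from-visit year - ``start_year`` + 1, so a 2010-2015 window
    yields cycles 1..5.  A subject with k consecutive annual visits yields
    k - 1 pairs; gaps > 1 year contribute nothing.

    Returns a tidy frame with columns ``subject_id``, ``sex``, ``age_band``,
    ``cycle``, ``from_state``, ``to_state``.
    """
    df = cohort.sort_values(["subject_id", "visit_year"], kind="mergesort")
    if "state" not in df.columns:
        raise InputError("cohort has no 'state' column; classify it first")
    same = df["subject_id"].eq(df["subject_id"].shift(-1))
    gap1 = df["visit_year"].shift(-1).sub(df["visit_year"]).eq(1)
    take = same & gap1 & df["state"].notna() & df["state"].shift(-1).notna()

    pairs = pd.DataFrame({
        "subject_id": df.loc[take, "subject_id"].values,
        "sex": df.loc[take, "sex"].values,
        "age_band": (df.loc[take, "age_band"].values
                     if "age_band" in df.columns else None),
        "cycle": (df.loc[take, "visit_year"].astype(int) - start_year + 1).values,
        "from_state": df.loc[take, "state"].values,
        "to_state": df["state"].shift(-1).loc[take].values,
    })
    return pairs.reset_index(drop=True)


def trajectories(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject trajectory summary: stratum, baseline year, and the ordered
    (visit_year, state) sequence as a list column."""
    df = cohort.sort_values(["subject_id", "visit_year"], kind="mergesort")
    agg = df.groupby("subject_id").agg(
        sex=("sex", "first"),
        baseline_year=("visit_year", "first"),
        baseline_age=("age", "first"),
        years=("visit_year", list),
        states=("state", list),
    )
    agg["stratum"] = [
        assign_stratum(s, a).key for s, a in zip(agg["sex"], agg["baseline_age"])
    ]
    return agg.reset_index()
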