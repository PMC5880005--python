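"""CDS-criteria classification of health-check-up records.

Cut-offs (Chinese Diabetes Society, 2004): overweight/obesity BMI >= 25.0
kg/m2; hypertension SBP >= 140 or DBP >= 90 mmHg or anti-hypertensive
medication; dyslipidemia fasting TG >= 1.7 mmol/L or HDL-C < 0.9 (men) /
< 1.0 (women) mmol/L; hyperglycemia FPG >= 6.1 mmol/L or 2-h post-meal
glucose >= 7.8 mmol/L or anti-hyperglycemic medication.

Boundary equality follows the inequality direction of each criterion: a value
exactly at the cut-off is positive for ">=" criteria and negative for the
strict "<" HDL criterion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .states import ComponentProfile, InputError, MetabolicState, Sex, state_of

__all__ = [
    "CheckupRecord",
    "ClassificationError",
    "diagnose_components",
    "classify_table",
    "CUTOFFS",
    "RECORD_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Diagnostic cut-offs, all in the units of the corresponding field.
CUTOFFS = {
    "bmi": 25.0,          # kg/m2, >=
    "sbp": 140.0,         # mmHg, >=
    "dbp": 90.0,          # mmHg, >=
    "tg": 1.7,            # mmol/L, >=
    "hdl_male": 0.9,      # mmol/L, strictly <
    "hdl_female": 1.0,    # mmol/L, strictly <
    "fpg": 6.1,           # mmol/L, >=
    "pg2h": 7.8,          # mmol/L, >=
}

# tolerated difference between a supplied BMI and height/weight-derived BMI
_BMI_RECOMPUTE_TOL = 0.1

#: CSV schema for one subject-visit row (pg2h and height/weight optional).
RECORD_COLUMNS = [
    "subject_id",
    "visit_year",
    "age",
    "sex",
    "bmi",
    "sbp",
    "dbp",
    "tg",
    "hdl",
    "fpg",
    "pg2h",
    "on_antihypertensive",
    "on_antihyperglycemic",
    "has_chd",
    "has_t1dm",
    "has_familial_hyperlipidemia",
]

_REQUIRED_FIELDS = ("bmi", "sbp", "dbp", "tg", "hdl", "fpg")


class ClassificationError(ValueError):
    """A record cannot be classified; the message names the offending field."""


@dataclass
class CheckupRecord:
    """One subject-visit with raw clinical measurements and history flags."""

    subject_id: str
    visit_year: int
    age: float
    sex: Sex
    bmi: Optional[float] = None
    sbp: float = math.nan
    dbp: float = math.nan
    tg: float = math.nan
    hdl: float = math.nan
    fpg: float = math.nan
    pg2h: Optional[float] = None
    on_antihypertensive: bool = False
    on_antihyperglycemic: bool = False
    has_chd: bool = False
    has_t1dm: bool = False
    has_familial_hyperlipidemia: bool = False
    height: Optional[float] = None   # m
    weight: Optional[float] = None   # kg

    def __post_init__(self) -> None:
        self.sex = Sex.parse(self.sex)


def _effective_bmi(record: CheckupRecord) -> float:
    """BMI = weight / height^2 when both are present; it overrides a supplied
    bmi field that disagrees by more than 0.1 kg/m2 (the discrepancy is
    logged)."""
    if record.height is not None and record.weight is not None:
        computed = record.weight / record.height**2
        if record.bmi is not None and abs(record.bmi - computed) > _BMI_RECOMPUTE_TOL:
            logger.warning(
                "subject %s, year %s: supplied bmi %.2f disagrees with "
                "height/weight-derived %.2f; using the derived value",
                record.subject_id, record.visit_year, record.bmi, computed,
            )
        return computed
    if record.bmi is None:
        raise ClassificationError("missing required field: bmi (no height/weight)")
    return record.bmi


def diagnose_components(record: CheckupRecord) -> ComponentProfile:
    """Diagnose the four CDS components for one check-up record.

    Medication flags substitute only for their own component: anti-hypertensive
    use implies hypertension, anti-hyperglycemic use implies hyperglycemia.
    ``pg2h`` is optional; when absent, hyperglycemia is decided from FPG and
    medication alone.

    Raises
    ------
    ClassificationError
        If a required measurement is missing (NaN); the message names it.
    InputError
        If the sex label is not ``male``/``female``.
    """
    sex = Sex.parse(record.sex)
    bmi = _effective_bmi(record)
    values = {"bmi": bmi, "sbp": record.sbp, "dbp": record.dbp,
              "tg": record.tg, "hdl": record.hdl, "fpg": record.fpg}
    for name in _REQUIRED_FIELDS:
        v = values[name]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ClassificationError(f"missing required field: {name}")

    hdl_cut = CUTOFFS["hdl_male"] if sex is Sex.MALE else CUTOFFS["hdl_female"]
    pg2h = record.pg2h
    has_pg2h = pg2h is not None and not (isinstance(pg2h, float) and math.isnan(pg2h))

    return ComponentProfile(
        overweight_obesity=bmi >= CUTOFFS["bmi"],
        hypertension=(
            record.sbp >= CUTOFFS["sbp"]
            or record.dbp >= CUTOFFS["dbp"]
            or bool(record.on_antihypertensive)
        ),
        dyslipidemia=record.tg >= CUTOFFS["tg"] or record.hdl < hdl_cut,
        hyperglycemia=(
            record.fpg >= CUTOFFS["fpg"]
            or (has_pg2h and pg2h >= CUTOFFS["pg2h"])
            or bool(record.on_antihyperglycemic)
        ),
    )


def classify_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification of a check-up table.

    Parameters
    ----------
    df
        One row per subject-visit with the :data:`RECORD_COLUMNS` schema
        (``pg2h``, ``height``, ``weight`` may be absent or NaN).

    Returns
    -------
    The input copied and augmented with the four boolean component columns
    and a ``state`` column holding the 12 state labels.  Rows with missing
    required measurements get ``state = NaN`` (the cohort builder excludes
    them); this function does not raise on them so that eligibility reporting
    can count them.
    """
    out = df.copy()
    sex = out["sex"].astype(str).str.strip().str.lower()
    bad_sex = ~sex.isin([s.value for s in Sex])
    if bad_sex.any():
        raise InputError(
            f"unknown sex label(s): {sorted(out.loc[bad_sex, 'sex'].unique())}"
        )

    bmi = pd.to_numeric(out["bmi"], errors="coerce")
    if {"height", "weight"}.issubset(out.columns):
        height = pd.to_numeric(out["height"], errors="coerce")
        weight = pd.to_numeric(out["weight"], errors="coerce")
        derived = weight / height**2
        use = derived.notna()
        n_conflict = int((use & bmi.notna() & ((bmi - derived).abs() > _BMI_RECOMPUTE_TOL)).sum())
        if n_conflict:
            logger.warning(
                "%d rows: supplied bmi disagrees with height/weight-derived "
                "value by > %.1f kg/m2; using the derived value",
                n_conflict, _BMI_RECOMPUTE_TOL,
            )
        bmi = derived.where(use, bmi)

    num = {c: pd.to_numeric(out[c], errors="coerce")
           for c in ("sbp", "dbp", "tg", "hdl", "fpg")}
    pg2h = (pd.to_numeric(out["pg2h"], errors="coerce")
            if "pg2h" in out.columns else pd.Series(np.nan, index=out.index))

    def flag(col: str, default: bool = False) -> pd.Series:
        if col not in out.columns:
            return pd.Series(default, index=out.index)
        return out[col].fillna(default).astype(bool)

    hdl_cut = np.where(sex == Sex.MALE.value,
                       CUTOFFS["hdl_male"], CUTOFFS["hdl_female"])
    ow = bmi >= CUTOFFS["bmi"]
    htn = ((num["sbp"] >= CUTOFFS["sbp"]) | (num["dbp"] >= CUTOFFS["dbp"])
           | flag("on_antihypertensive"))
    dys = (num["tg"] >= CUTOFFS["tg"]) | (num["hdl"] < hdl_cut)
    hyp = ((num["fpg"] >= CUTOFFS["fpg"]) | (pg2h >= CUTOFFS["pg2h"])
           | flag("on_antihyperglycemic"))

    complete = bmi.notna()
    for c in ("sbp", "dbp", "tg", "hdl", "fpg"):
        complete &= num[c].notna()

    out["overweight_obesity"] = ow
    out["hypertension"] = htn
    out["dyslipidemia"] = dys
    out["hyperglycemia"] = hyp

    # map flag quadruples to state labels via the canonical total map
    code = (ow.astype(int) + 2 * htn.astype(int)
            + 4 * dys.astype(int) + 8 * hyp.astype(int))
    lut = {}
    for i in range(16):
        p = ComponentProfile(*(bool(i >> k & 1) for k in range(4)))
        lut[i] = state_of(p).value
    out["state"] = code.map(lut)
    out.loc[~complete, "state"] = np.nan
    return out


def classify_csv(path, out_path=None) -> pd.DataFrame:
    """Read a check-up CSV, classify it, and optionally write the augmented
    table (empty pg2h fields are treated as absent)."""
    df = pd.read_csv(path)
    result = classify_table(df)
    if out_path is not None:
        result.to_csv(out_path, index=False)
    return result


def state_label(profile: ComponentProfile) -> MetabolicState:
    # thin alias kept for symmetry with diagnose_components
    return state_of(profile)
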