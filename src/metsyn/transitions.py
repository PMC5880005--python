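"""Annual transition-probability estimation and published reference matrices.

The estimator follows the cycle-averaged design: within each stratum, each of
the five annual cycles yields a 12x12 proportion matrix (row i, column j =
observed fraction of subjects in state i at the start of the cycle who are in
state j one year later), and the model's transition matrix is the arithmetic
mean of the per-cycle matrices over the cycles in which each row is defined.
Rows are renormalised to sum to 1 after averaging.

Published reference matrices for the four sex x age-band strata ship as JSON
fixtures and can be loaded with :func:`load_printed_matrix`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import Stratum
from .states import STATE_ORDER, InputError, MetabolicState

__all__ = [
    "N_STATES",
    "TransitionMatrix",
    "FixtureIntegrityError",
    "cycle_matrix",
    "mean_matrix",
    "estimate_matrices",
    "load_printed_matrix",
    "FIXTURE_NAMES",
    "N_CYCLES",
]

logger = logging.getLogger(__name__)

N_STATES = 12
N_CYCLES = 5
_LABELS = [s.value for s in STATE_ORDER]

FIXTURE_NAMES = ("men_18_49", "women_18_49", "men_50plus", "women_50plus")

#: Printed row sums may deviate from 100 by at most this much (percent).
ROW_SUM_TOL_PCT = 0.05
#: Row-stochasticity tolerance after normalisation.
ROW_STOCHASTIC_TOL = 1e-9


class FixtureIntegrityError(ValueError):
    """A reference matrix fails its integrity check; the message names the row."""


@dataclass
class TransitionMatrix:
    """A 12x12 row-stochastic annual transition matrix for one stratum.

    Attributes
    ----------
    stratum:
        Canonical stratum key (``men_18_49`` etc.) or any label.
    probs:
        (12, 12) array, row = from-state, column = to-state; rows sum to 1.
    counts:
        Optional (12, 12) integer array of pooled transition counts.
    per_cycle:
        Optional list of ``(proportions, denominators)`` tuples, one per
        cycle; undefined rows are NaN.
    filled_rows:
        States whose row was observed in no cycle and was set to the identity
        row (self-retention 1).
    """

    stratum: str
    probs: np.ndarray
    counts: np.ndarray | None = None
    per_cycle: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    filled_rows: tuple[MetabolicState, ...] = ()
    source: str = "estimated"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.probs.shape != (N_STATES, N_STATES):
            raise InputError(f"matrix shape {self.probs.shape} != (12, 12)")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise InputError("transition probabilities outside [0, 1]")
        dev = np.abs(self.probs.sum(axis=1) - 1.0)
        if dev.max() > ROW_STOCHASTIC_TOL:
            bad = _LABELS[int(dev.argmax())]
            raise InputError(
                f"row {bad} sums to 1{dev.max():+.2e}; matrix is not row-stochastic"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=_LABELS, columns=_LABELS)

    def to_json(self, path=None) -> str:
        payload: dict = {
            "stratum": self.stratum,
            "source": self.source,
            "states": _LABELS,
            "probs": self.probs.tolist(),
        }
        if self.counts is not None:
            payload["counts"] = np.asarray(self.counts).astype(int).tolist()
        if self.filled_rows:
            payload["filled_rows"] = [s.value for s in self.filled_rows]
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _tally(pairs: pd.DataFrame) -> np.ndarray:
    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    idx = {lab: i for i, lab in enumerate(_LABELS)}
    i = pairs["from_state"].map(idx).to_numpy()
    j = pairs["to_state"].map(idx).to_numpy()
    np.add.at(counts, (i, j), 1)
    return counts


def cycle_matrix(
    pairs: pd.DataFrame, cycle: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle transition-proportion matrix and row denominators.

    Entry (i, j) = (# pairs from state i to state j in this cycle) /
    (# pairs from state i in this cycle).  Rows with zero denominator are NaN
    (undefined), never zero.  ``pairs`` must belong to a single stratum.
    """
    if not 1 <= int(cycle) <= N_CYCLES:
        raise InputError(f"cycle {cycle} outside 1..{N_CYCLES}")
    sub = pairs[pairs["cycle"] == int(cycle)]
    counts = _tally(sub) if len(sub) else np.zeros((N_STATES, N_STATES), np.int64)
    denom = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts / denom[:, None]
    props[denom == 0] = np.nan
    return props, denom


def mean_matrix(
    cycles: list[tuple[np.ndarray, np.ndarray]],
    stratum: str = "estimated",
) -> TransitionMatrix:
    """Average per-cycle proportion matrices into a model transition matrix.

    Each row is the arithmetic mean over the cycles in which it is defined
    (zero-denominator rows are excluded from the mean, not averaged as zeros),
    then renormalised to sum to 1.  Rows defined in no cycle are set to the
    identity row (self-retention 1) and flagged in ``filled_rows``.
    """
    if not cycles:
        raise InputError("no per-cycle matrices to average")
    stack = np.stack([p for p, _ in cycles])  # (n_cycles, 12, 12)
    with warnings.catch_warnings():
        # all-NaN rows are expected: they are the never-observed rows
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    row_sums = mean.sum(axis=1)
    undefined = np.isnan(row_sums)

    dev = np.abs(row_sums[~undefined] - 1.0)
    if dev.size and dev.max() > 1e-12:
        logger.info("max row-sum deviation before renormalisation: %.3e", dev.max())
    mean[~undefined] /= row_sums[~undefined, None]

    filled = []
    for i in np.flatnonzero(undefined):
        mean[i] = 0.0
        mean[i, i] = 1.0
        filled.append(STATE_ORDER[i])
    if filled:
        logger.warning(
            "stratum %s: rows never observed, set to identity: %s",
            stratum, [s.value for s in filled],
        )

    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    for p, d in cycles:
        c = np.where(np.isnan(p), 0.0, p) * d[:, None]
        counts += np.rint(c).astype(np.int64)

    return TransitionMatrix(
        stratum=stratum,
        probs=mean,
        counts=counts,
        per_cycle=list(cycles),
        filled_rows=tuple(filled),
    )


def estimate_matrices(
    pairs: pd.DataFrame, n_cycles: int = N_CYCLES
) -> dict[str, TransitionMatrix]:
    """Estimate one cycle-averaged matrix per stratum from a pair table.

    ``pairs`` needs columns ``sex``, ``age_band``, ``cycle``, ``from_state``,
    ``to_state`` (the output of :func:`metsyn.cohort.extract_pairs` on a
    stratified cohort).  Returns a dict keyed by canonical stratum key.
    """
    out: dict[str, TransitionMatrix] = {}
    for (sex, band), sub in pairs.groupby(["sex", "age_band"], sort=True):
        key = Stratum(sex, band).key
        cycles = []
        for c in range(1, n_cycles + 1):
            props, denom = cycle_matrix(sub, c)
            if denom.sum() > 0:
                cycles.append((props, denom))
        out[key] = mean_matrix(cycles, stratum=key)
    return out


def _load_fixture_payload(name: str) -> dict:
    if name not in FIXTURE_NAMES:
        raise InputError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}"
        )
    ref = resources.files("metsyn.data").joinpath(f"transition_{name}.json")
    return json.loads(ref.read_text())


def load_printed_matrix(
    name: str, alternate_corrupt_cell: bool = False
) -> TransitionMatrix:
    """Load one of the four published reference matrices.

    Entries are converted from percent to proportion; every row is validated
    to sum to 100 within +/- 0.05 before conversion and renormalised after.

    The ``men_18_49`` isolated-hyperglycemia row contains one cell that is
    typographically corrupt in the source table; the fixture resolves it as
    6.24% in the OW_HYP column (the row then sums to 99.99 and the analogous
    cell is nonzero in the other strata).  ``alternate_corrupt_cell=True``
    places the 6.24% in the OW_DYS column instead.
    """
    payload = _load_fixture_payload(name)
    if payload["states"] != _LABELS:
        raise FixtureIntegrityError(f"{name}: state labels out of order")
    pct = np.asarray(payload["percent"], dtype=float)
    if alternate_corrupt_cell:
        if name != "men_18_49":
            raise InputError("the corrupt-cell override applies to men_18_49 only")
        i = MetabolicState.HYP.index
        pct[i, MetabolicState.OW_DYS.index] = pct[i, MetabolicState.OW_HYP.index]
        pct[i, MetabolicState.OW_HYP.index] = 0.0
    row_sums = pct.sum(axis=1)
    for i, s in enumerate(row_sums):
        if abs(s - 100.0) > ROW_SUM_TOL_PCT:
            raise FixtureIntegrityError(
                f"{name}: row {_LABELS[i]} sums to {s:.2f}%, "
                f"outside 100 +/- {ROW_SUM_TOL_PCT}"
            )
    probs = pct / 100.0
    probs /= probs.sum(axis=1, keepdims=True)
    return TransitionMatrix(stratum=name, probs=probs, source="printed")


def load_all_printed_matrices() -> dict[str, TransitionMatrix]:
    """All four published reference matrices, keyed by stratum."""
    return {name: load_printed_matrix(name) for name in FIXTURE_NAMES}
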