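"""Forward propagation of the 12-state chain: risk prediction and validation.

Year 0 is a point mass on the starting state; the occupancy distribution at
year t is the year t-1 distribution multiplied by the annual transition
matrix, which is held constant over the horizon.  Two MS risk readings are
computed side by side:

``ms_occupancy``
    probability of being in the MS state at year t under the full reversible
    matrix (exits from MS allowed) — this is the model's "predictive rate"
    and is what point-prevalence validation compares against;
``ms_cumulative``
    probability of having ever entered MS by year t, computed with the MS row
    replaced by the absorbing row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import (ISOLATED_STATES, PAIR_STATES, STATE_ORDER,
                     InputError, MetabolicState)
from .transitions import N_STATES, TransitionMatrix

__all__ = [
    "RiskTrajectory",
    "predict",
    "risk_panel",
    "figure_splits",
    "validate",
    "plot_risk_panel",
]

_LABELS = [s.value for s in STATE_ORDER]
_MS = MetabolicState.MS.index


@dataclass
class RiskTrajectory:
    """State-occupancy trajectory from a fixed starting state.

    ``occupancy`` has shape (horizon + 1, 12); row 0 is the point mass on
    ``start_state``.  ``ms_occupancy`` and ``ms_cumulative`` are indexed the
    same way (entry 0 is 1 for an MS start, else 0).
    """

    stratum: str
    start_state: MetabolicState
    horizon: int
    occupancy: np.ndarray
    ms_occupancy: np.ndarray
    ms_cumulative: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-year export (years 0..horizon)."""
        return pd.DataFrame({
            "stratum": self.stratum,
            "start_state": self.start_state.value,
            "year": np.arange(self.horizon + 1),
            "ms_occupancy": self.ms_occupancy,
            "ms_cumulative": self.ms_cumulative,
        })


def _absorbing(probs: np.ndarray) -> np.ndarray:
    out = probs.copy()
    out[_MS] = 0.0
    out[_MS, _MS] = 1.0
    return out


def predict(
    matrix: TransitionMatrix,
    start_state: MetabolicState | str,
    horizon: int = 10,
) -> RiskTrajectory:
    """Propagate a point mass on ``start_state`` through ``matrix``.

    Raises a validation error before any propagation if the matrix is not
    row-stochastic, and requires ``horizon >= 1``.
    """
    matrix.validate()
    if horizon < 1:
        raise InputError(f"horizon must be >= 1, got {horizon}")
    start = MetabolicState(start_state)

    P = matrix.probs
    Pa = _absorbing(P)
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, start.index] = 1.0
    va = occ[0].copy()
    cum = np.zeros(horizon + 1)
    cum[0] = va[_MS]
    for t in range(1, horizon + 1):
        occ[t] = occ[t - 1] @ P
        va = va @ Pa
        cum[t] = va[_MS]
    return RiskTrajectory(
        stratum=matrix.stratum,
        start_state=start,
        horizon=horizon,
        occupancy=occ,
        ms_occupancy=occ[:, _MS].copy(),
        ms_cumulative=cum,
    )


def risk_panel(matrix: TransitionMatrix, horizon: int = 10) -> pd.DataFrame:
    """MS-risk curves for all 12 starting states, as a tidy frame.

    Columns: ``stratum``, ``start_state``, ``year`` (0..horizon),
    ``ms_occupancy``, ``ms_cumulative``.
    """
    frames = [predict(matrix, s, horizon).to_frame() for s in STATE_ORDER]
    return pd.concat(frames, ignore_index=True)


def figure_splits() -> dict[str, tuple[MetabolicState, ...]]:
    """The two start-state groups used for plotting: no-component plus
    isolated states, and no-component plus 2-component states.  The
    no-component curve appears in both."""
    return {
        "isolated": (MetabolicState.NONE, *ISOLATED_STATES),
        "pairs": (MetabolicState.NONE, *PAIR_STATES),
    }


def validate(
    matrix: TransitionMatrix,
    cohort: pd.DataFrame,
    start_state: MetabolicState | str | None = None,
    years: int | list[int] = 5,
) -> pd.DataFrame:
    """Compare model-predicted MS occupancy with empirical MS prevalence.

    For each requested starting state and follow-up length, the empirical
    value is the fraction of cohort subjects observed in MS exactly ``years``
    years after baseline, among those whose baseline state is the starting
    state.  The predicted value is ``ms_occupancy`` at that year from
    :func:`predict`.  Cells with no subjects at the required follow-up are
    flagged empty rather than raising.

    ``cohort`` must carry ``subject_id``, ``visit_year`` and ``state``
    columns (classified and eligibility-filtered).
    """
    starts = (list(STATE_ORDER) if start_state is None
              else [MetabolicState(start_state)])
    year_list = [years] if np.isscalar(years) else list(years)

    df = cohort.sort_values(["subject_id", "visit_year"], kind="mergesort")
    grp = df.groupby("subject_id")
    base_year = grp["visit_year"].transform("first")
    offset = (df["visit_year"] - base_year).astype(int)
    base_state = grp["state"].transform("first")

    rows = []
    for s in starts:
        in_start = base_state == s.value
        traj = predict(matrix, s, horizon=max(year_list))
        for y in year_list:
            at_y = df[in_start & (offset == y)]
            n = len(at_y)
            empirical = (at_y["state"] == MetabolicState.MS.value).mean() if n else np.nan
            rows.append({
                "stratum": matrix.stratum,
                "start_state": s.value,
                "years": y,
                "predicted_pct": round(100 * traj.ms_occupancy[y], 2),
                "empirical_pct": round(100 * empirical, 2) if n else np.nan,
                "n_subjects": n,
                "empty": n == 0,
            })
    return pd.DataFrame(rows)


def plot_risk_panel(matrix: TransitionMatrix, horizon: int = 10,
                    which: str = "isolated", ax=None):
    """Plot MS predictive-rate curves (percent, years 1..horizon) for one of
    the two figure splits; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    states = figure_splits()[which]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    years = np.arange(1, horizon + 1)
    for s in states:
        traj = predict(matrix, s, horizon)
        ax.plot(years, 100 * traj.ms_occupancy[1:], marker="o", ms=3,
                label=s.value)
    ax.set_xlabel("years after the initial state")
    ax.set_ylabel("predictive rate of MS (%)")
    ax.set_title(matrix.stratum)
    ax.legend(fontsize=8)
    return ax
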