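"""Nelson–Aalen and Kaplan–Meier estimation with delayed entry.

Both estimators are driven by the risk-set count ``Y(u) = #{i : entry_i < u <=
exit_i}`` and the event count ``dN(u)`` at each distinct observed event time.
The ``entry < u <= exit`` convention is the single at-risk convention used
everywhere in this package; with it, subjects censored at ``u`` are still in
``Y(u)``, i.e. events are processed before censorings at tied times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StepFunctionCurve:
    """Right-continuous step function produced by NA or KM estimation.

    ``values[k]`` is the estimate at and after ``jump_times[k]``;
    ``baseline`` (0 for a cumulative hazard, 1 for a survival curve) applies
    before the first jump.  ``increments`` holds the per-jump hazard increments
    ``dN(u)/Y(u)`` and ``at_risk`` the risk-set size ``Y(u)``.
    """

    jump_times: np.ndarray
    values: np.ndarray
    at_risk: np.ndarray
    increments: np.ndarray
    baseline: float = 0.0
    variance: np.ndarray | None = field(default=None, repr=False)

    def __call__(self, t):
        """Evaluate the curve at (scalar or array) times ``t``."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, float), side="right")
        padded = np.concatenate([[self.baseline], self.values])
        return padded[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.jump_times,
                "value": self.values,
                "at_risk": self.at_risk,
                "increment": self.increments,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _risk_table(intervals: pd.DataFrame):
    entry = intervals["entry"].to_numpy(float)
    exit_ = intervals["exit"].to_numpy(float)
    event = intervals["event"].to_numpy(bool)
    if np.any(entry >= exit_):
        raise ValueError("intervals must satisfy entry < exit")
    times, d = np.unique(exit_[event], return_counts=True)
    # Y(u) = #{entry < u <= exit}, vectorised via sorted entry/exit arrays
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    n_entered = np.searchsorted(entry_sorted, times, side="left")
    n_left = np.searchsorted(exit_sorted, times, side="left")
    at_risk = n_entered - n_left
    assert np.all(at_risk >= d), "risk set smaller than event count"
    return times, at_risk.astype(int), d.astype(int)


def nelson_aalen(intervals: pd.DataFrame, variance: bool = False) -> StepFunctionCurve:
    """Nelson–Aalen estimator of the cumulative hazard,
    ``A_hat(t) = sum_{u <= t} dN(u) / Y(u)``.

    Supports delayed entry, so it is valid on the calendar scale where
    subjects are left-truncated at their admission day.
    """
    times, at_risk, d = _risk_table(intervals)
    if len(times) == 0:
        raise ValueError("no events observed; Nelson-Aalen curve is degenerate")
    inc = d / at_risk
    var = np.cumsum(d / at_risk.astype(float) ** 2) if variance else None
    return StepFunctionCurve(
        jump_times=times,
        values=np.cumsum(inc),
        at_risk=at_risk,
        increments=inc,
        baseline=0.0,
        variance=var,
    )


def kaplan_meier(intervals: pd.DataFrame, variance: bool = False) -> StepFunctionCurve:
    """Kaplan–Meier estimator ``S_hat(t) = prod_{u <= t} (1 - dN(u)/Y(u))``.

    Intended for the patient-time scale, where all subjects share time zero.
    Called on left-truncated (calendar-scale) intervals it still computes the
    product-limit formula but emits a warning: without a common origin the
    curve does not estimate a survival function.
    """
    if np.any(intervals["entry"].to_numpy(float) != 0):
        warnings.warn(
            "Kaplan-Meier called on intervals with delayed entry; a survival "
            "curve on the calendar scale is not interpretable",
            stacklevel=2,
        )
    entry = intervals["entry"].to_numpy(float)
    exit_ = intervals["exit"].to_numpy(float)
    event = intervals["event"].to_numpy(bool)
    if np.any(entry >= exit_):
        raise ValueError("intervals must satisfy entry < exit")
    if not event.any():
        times = np.array([exit_.max()])
        ones = np.ones(1)
        n0 = int(np.sum((entry < times[0]) & (times[0] <= exit_)))
        return StepFunctionCurve(times, ones, np.array([n0]), np.zeros(1), baseline=1.0)
    times, at_risk, d = _risk_table(intervals)
    inc = d / at_risk
    surv = np.cumprod(1.0 - inc)
    var = None
    if variance:  # Greenwood
        with np.errstate(divide="ignore", invalid="ignore"):
            var = surv**2 * np.cumsum(d / (at_risk * (at_risk - d)).astype(float))
    return StepFunctionCurve(
        jump_times=times,
        values=surv,
        at_risk=at_risk,
        increments=inc,
        baseline=1.0,
        variance=var,
    )
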