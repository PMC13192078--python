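"""Piecewise-constant hazard approximation on the patient-time scale.

The hazard of group *j* is parametrised as

    alpha_j(t) = sum_k 1(t_{k-1} < t <= t_k) * alpha_{j,k},

with cut points ``0 = t_0 < t_1 < ... < t_K``.  Two fitting routes are
provided: ``occurrence_exposure`` (events / person-time per interval, the
piecewise-exponential maximum-likelihood rates) and ``na_slope`` (slopes of a
continuous piecewise-linear least-squares fit to the Nelson–Aalen curve,
mirroring the geometric construction of approximating the cumulative hazard
by straight-line segments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nonparam import nelson_aalen


@dataclass
class PiecewiseConstantHazard:
    """Hazard constant on intervals ``(t_{k-1}, t_k]``.

    ``cut_points`` includes the leading 0, so ``len(cut_points) ==
    len(rates) + 1``.  Evaluation is half-open on the left: the upper cut
    belongs to its interval, and the hazard is 0 beyond the last cut and at
    ``t <= 0`` (hazards live on positive times).
    """

    cut_points: np.ndarray
    rates: np.ndarray
    group: str | None = None
    n_events: np.ndarray | None = field(default=None, repr=False)
    person_time: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.cut_points = np.asarray(self.cut_points, float)
        self.rates = np.asarray(self.rates, float)
        if self.cut_points[0] != 0:
            raise ValueError("cut_points must start at 0")
        if np.any(np.diff(self.cut_points) <= 0):
            raise ValueError("cut_points must be strictly increasing")
        if len(self.rates) != len(self.cut_points) - 1:
            raise ValueError("need exactly one rate per interval")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    def __call__(self, t):
        return evaluate_hazard(self, t)

    def cumulative(self, t):
        return cumulative_hazard(self, t)

    @property
    def total_cumulative(self) -> float:
        """A(t_K), the cumulative hazard over the whole support."""
        return float(np.sum(self.rates * np.diff(self.cut_points)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_lo": self.cut_points[:-1],
                "t_hi": self.cut_points[1:],
                "rate": self.rates,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group=None) -> "PiecewiseConstantHazard":
        df = df.sort_values("t_lo")
        cuts = np.concatenate([df["t_lo"].to_numpy(float)[:1], df["t_hi"].to_numpy(float)])
        return cls(cut_points=cuts, rates=df["rate"].to_numpy(float), group=group)


def evaluate_hazard(pwh: PiecewiseConstantHazard, t):
    """alpha(t) for ``t > 0``; 0 beyond the last cut point.

    A boundary value ``t = t_k`` belongs to the interval to its left.
    """
    t_arr = np.asarray(t, float)
    if np.any(t_arr <= 0):
        raise ValueError("hazard is defined on positive times only")
    idx = np.searchsorted(pwh.cut_points, t_arr, side="left") - 1
    rates = np.concatenate([pwh.rates, [0.0]])
    idx = np.clip(idx, 0, len(pwh.rates))
    out = rates[idx]
    return out if np.ndim(t) else float(out)


def cumulative_hazard(pwh: PiecewiseConstantHazard, t):
    """A(t) = integral of the hazard over (0, t]; piecewise linear in ``t``."""
    t_arr = np.atleast_1d(np.asarray(t, float))
    if np.any(t_arr < 0):
        raise ValueError("cumulative hazard requires t >= 0")
    lo = pwh.cut_points[:-1]
    hi = pwh.cut_points[1:]
    overlap = np.clip(t_arr[:, None], lo, hi) - lo  # time spent in each interval
    vals = overlap @ pwh.rates
    return vals if np.ndim(t) else float(vals[0])


def _person_time_and_events(intervals: pd.DataFrame, cut_points: np.ndarray):
    entry = intervals["entry"].to_numpy(float)
    exit_ = intervals["exit"].to_numpy(float)
    event = intervals["event"].to_numpy(bool)
    lo = cut_points[:-1]
    hi = cut_points[1:]
    pt = (
        np.clip(exit_[:, None], lo, hi) - np.clip(entry[:, None], lo, hi)
    ).sum(axis=0)
    # event assigned to the interval containing the exit: (t_{k-1}, t_k]
    idx = np.searchsorted(cut_points, exit_[event], side="left") - 1
    d = np.bincount(idx, minlength=len(lo)).astype(float)
    return pt, d


def fit_piecewise_hazard(
    intervals: pd.DataFrame,
    cut_points,
    method: str = "occurrence_exposure",
    group: str | None = None,
) -> PiecewiseConstantHazard:
    """Fit per-interval constant hazards from patient-time intervals.

    ``occurrence_exposure``: rate_k = events_k / person-time_k, the MLE of the
    piecewise-exponential model.  ``na_slope``: least-squares slopes of a
    continuous piecewise-linear function through the Nelson–Aalen jump points.
    The last cut point must reach the largest observed exit time.
    """
    cut_points = np.asarray(cut_points, float)
    if cut_points[0] != 0:
        cut_points = np.concatenate([[0.0], cut_points])
    if np.any(np.diff(cut_points) <= 0):
        raise ValueError("cut points must be strictly increasing")
    max_exit = float(intervals["exit"].max())
    if cut_points[-1] < max_exit:
        raise ValueError(
            f"last cut point {cut_points[-1]} is below the largest observed "
            f"exit time {max_exit}"
        )
    pt, d = _person_time_and_events(intervals, cut_points)
    if method == "occurrence_exposure":
        rates = np.zeros_like(pt)
        dead_intervals = pt <= 0
        if np.any(dead_intervals & (d > 0)):
            raise ValueError("events in an interval with zero person-time")
        if np.any(dead_intervals):
            warnings.warn(
                "interval(s) with zero person-time; rate set to 0", stacklevel=2
            )
        np.divide(d, pt, out=rates, where=~dead_intervals)
    elif method == "na_slope":
        curve = nelson_aalen(intervals)
        # A(t) = sum_k alpha_k * len((t_{k-1}, t_k] ∩ (0, t]) is linear in the
        # rates; solve the equally-weighted least-squares problem over the NA
        # jump points, which enforces continuity and A(0)=0 by construction.
        lo, hi = cut_points[:-1], cut_points[1:]
        design = np.clip(curve.jump_times[:, None], lo, hi) - lo
        rates, *_ = np.linalg.lstsq(design, curve.values, rcond=None)
        if np.any(rates < -1e-12):
            warnings.warn(
                "negative na_slope rate(s) clipped to 0", stacklevel=2
            )
        rates = np.clip(rates, 0.0, None)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PiecewiseConstantHazard(
        cut_points=cut_points,
        rates=rates,
        group=group,
        n_events=d,
        person_time=pt,
    )


def default_cut_points(intervals: pd.DataFrame, n_intervals: int = 4) -> np.ndarray:
    """Heuristic cut points: quantiles of the observed event times, with the
    last cut at the maximum exit time.  A pragmatic default — study-specific
    cut points should be chosen by the analyst where available.
    """
    event_times = intervals.loc[intervals["event"], "exit"].to_numpy(float)
    if len(event_times) == 0:
        raise ValueError("no events; cannot place cut points")
    qs = np.quantile(event_times, np.linspace(0, 1, n_intervals + 1)[1:-1])
    cuts = np.concatenate([[0.0], np.unique(qs), [float(intervals["exit"].max())]])
    if np.any(np.diff(cuts) <= 0):
        cuts = np.unique(cuts)
    return cuts
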