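"""Transforming group hazards from patient time to calendar time.

Given a piecewise-constant group hazard ``alpha_j(t)`` in patient time, the
individual calendar-time hazard of subject *i* admitted on day ``c*_i`` is

    alpha_bar_i(c) = 1(c >= c*_i) * alpha_j(c - c*_i),

and the empirical population hazard of group *j* at calendar time ``c`` is the
arithmetic mean of ``alpha_bar_i(c)`` over the group's subjects at risk at
``c`` (at-risk: ``c*_i < c <= c*_i + T*_i``).  The ratio of two population
hazards gives the time-dependent empirical hazard ratio on the calendar scale
— the diagnostic that makes the structural bias of the calendar time scale
visible: with decreasing hazards and one group entering earlier, the earlier
group's population hazard has had more time to decay at any shared ``c``.

At ``c = c*_i`` exactly the subject contributes nothing: the hazard at
patient time 0 is taken as 0 and the at-risk indicator is strict on the left.
Grid points where a group has no subject at risk are explicitly undefined
(masked), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .hazard_approx import PiecewiseConstantHazard


@dataclass
class PopulationHazardCurve:
    """Per-group calendar-time population hazard on a grid.

    ``values`` are NaN (and ``defined`` False) wherever ``n_at_risk`` is 0.
    """

    grid: np.ndarray
    values: np.ndarray
    n_at_risk: np.ndarray
    group: str

    @property
    def defined(self) -> np.ndarray:
        return self.n_at_risk > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c": self.grid,
                "value": self.values,
                "n_at_risk": self.n_at_risk,
                "defined": self.defined,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class HazardRatioCurve:
    grid: np.ndarray
    values: np.ndarray
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"c": self.grid, "value": self.values, "defined": self.defined}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def individual_hazard_calendar(
    pwh: PiecewiseConstantHazard, c_star: float, c
) -> np.ndarray | float:
    """Individual calendar-time hazard: ``1(c >= c*) * alpha(c - c*)``,
    with ``alpha(0)`` taken as 0 (hazards live on positive patient times)."""
    c_arr = np.atleast_1d(np.asarray(c, float))
    t = c_arr - c_star
    out = np.zeros_like(t)
    pos = t > 0
    if pos.any():
        out[pos] = pwh(t[pos])
    return out if np.ndim(c) else float(out[0])


def population_hazard_calendar(
    pwh_by_group: Mapping[str, PiecewiseConstantHazard],
    cohort: pd.DataFrame,
    grid: np.ndarray | None = None,
    chunk: int = 256,
) -> dict[str, PopulationHazardCurve]:
    """Empirical parametric population hazard per group on a calendar grid.

    The default grid covers integer calendar days from each group's first
    study entry to its last exit; a shared grid can be passed explicitly.
    Subjects enter the average strictly after their admission day and leave
    after ``c* + T*``.
    """
    curves: dict[str, PopulationHazardCurve] = {}
    for group, pwh in pwh_by_group.items():
        sub = cohort[cohort["group"] == group]
        if len(sub) == 0:
            raise ValueError(f"no subjects in group {group!r}")
        c_star = sub["admission_day"].to_numpy(float)
        c_out = c_star + sub["followup_time"].to_numpy(float)
        if grid is None:
            g = np.arange(np.floor(c_star.min()) + 1, np.ceil(c_out.max()) + 1)
        else:
            g = np.asarray(grid, float)
        values = np.full(len(g), np.nan)
        n_at_risk = np.zeros(len(g), dtype=int)
        for start in range(0, len(g), chunk):
            gc = g[start : start + chunk, None]  # (chunk, 1) vs (n,) subjects
            at_risk = (c_star < gc) & (gc <= c_out)
            t = gc - c_star
            haz = np.zeros_like(t)
            pos = t > 0
            if pos.any():
                haz[pos] = pwh(t[pos])
            n = at_risk.sum(axis=1)
            sl = slice(start, start + len(gc))
            n_at_risk[sl] = n
            with np.errstate(invalid="ignore"):
                values[sl] = np.where(
                    n > 0, (haz * at_risk).sum(axis=1) / np.maximum(n, 1), np.nan
                )
        values[n_at_risk == 0] = np.nan
        curves[group] = PopulationHazardCurve(
            grid=g, values=values, n_at_risk=n_at_risk, group=group
        )
    return curves


def empirical_hazard_ratio(
    curve_num: PopulationHazardCurve, curve_den: PopulationHazardCurve
) -> HazardRatioCurve:
    """Pointwise ratio of two population hazards on a shared grid.

    Defined only where both curves are defined and the denominator is
    positive; undefined points carry NaN, never 0 or infinity.
    """
    if len(curve_num.grid) != len(curve_den.grid) or not np.array_equal(
        curve_num.grid, curve_den.grid
    ):
        raise ValueError("curves must share the same calendar grid")
    defined = (
        curve_num.defined & curve_den.defined & (np.nan_to_num(curve_den.values) > 0)
    )
    values = np.full(len(curve_num.grid), np.nan)
    values[defined] = curve_num.values[defined] / curve_den.values[defined]
    return HazardRatioCurve(grid=curve_num.grid, values=values, defined=defined)


def plot_population_hazards(curves, ax=None):
    """Overlay per-group calendar-time population hazards (one line each)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for group, curve in curves.items():
        ax.plot(curve.grid, curve.values, label=group, drawstyle="steps-post")
    ax.set_xlabel("calendar time (days since 1970-01-01)")
    ax.set_ylabel("population hazard (events / day)")
    ax.legend()
    return ax


def plot_hazard_ratio(hr_curve: HazardRatioCurve, reference: float | None = 1.0, ax=None):
    """Plot the empirical calendar-time hazard-ratio curve with a reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(hr_curve.grid, hr_curve.values, drawstyle="steps-post")
    if reference is not None:
        ax.axhline(reference, color="grey", linestyle="--")
    ax.set_xlabel("calendar time (days since 1970-01-01)")
    ax.set_ylabel("hazard ratio")
    return ax
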