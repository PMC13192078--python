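"""Regression models on one or two time scales.

* :func:`cox_fit` — marginal Cox model on counting-process intervals with
  delayed entry and a cluster-robust (sandwich) variance, the workhorse for
  both the patient-time and the calendar-time scale.
* :func:`cox_two_scale_patient_time` / :func:`cox_two_scale_calendar` — Cox
  models that keep one scale as the nonparametric baseline and model the
  other parametrically as a covariate (fixed admission year, or time since
  admission updated weekly).
* :func:`lexis_split` + :func:`poisson_two_scale` — piecewise-exponential
  (Poisson) rate regression on cells of the Lexis diagram, treating both
  scales parametrically and symmetrically.
* :func:`ph_test` — Grambsch–Therneau score test for proportional hazards
  from scaled Schoenfeld residuals.

Partial-likelihood maximisation is delegated to :class:`statsmodels` PHReg
(which supports delayed entry, Efron/Breslow ties and grouped robust
variance); the Poisson model is a statsmodels GLM with a log person-time
offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.duration.hazard_regression import PHReg

from .data_model import GROUPS, to_counting_process

RESERVED_COLUMNS = {"subject_id", "entry", "exit", "event", "cluster_id"}

#: Default patient-time bands (days since admission) for two-scale models.
DEFAULT_T_CUTS = (0.0, 7.0, 30.0, 90.0, 180.0)


@dataclass
class RegressionResult:
    """Coefficients and cluster-robust inference from a Cox or Poisson fit.

    ``summary`` has one row per model term with columns ``coef`` (log
    hazard/rate ratio), ``hr``, ``se`` (robust where clustering was used),
    ``ci_low``/``ci_high`` (95 %, normal approximation on the log scale) and
    ``p``.
    """

    summary: pd.DataFrame
    n_events: int
    n_intervals: int
    converged: bool
    model_tag: str
    time_scale: str | None = None
    params: np.ndarray = field(default=None, repr=False)
    cov_params: np.ndarray = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        return float(self.summary.loc[term, "coef"])

    def hazard_ratio(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def ci95(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def p_value(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: ``model,time_scale,term,hr,ci_low,ci_high,p``."""
        out = self.summary.reset_index(names="term")
        out.insert(0, "model", self.model_tag)
        out.insert(1, "time_scale", self.time_scale or "")
        return out[["model", "time_scale", "term", "hr", "ci_low", "ci_high", "p"]]


def results_table(results) -> pd.DataFrame:
    """Concatenate several fits into one exportable results table."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)


def _design_matrix(intervals: pd.DataFrame, covariates) -> pd.DataFrame:
    """Expand covariate columns into a numeric design matrix; categorical
    columns become treatment dummies (reference: 'Pre' for the group column,
    first sorted level otherwise)."""
    if covariates is None:
        covariates = [c for c in intervals.columns if c not in RESERVED_COLUMNS]
    cols = {}
    for cov in covariates:
        col = intervals[cov]
        if col.dtype.kind in "OUS" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(pd.unique(col))
            if set(levels) <= set(GROUPS):
                order = [g for g in GROUPS if g in levels]
            else:
                order = sorted(levels)
            for level in order[1:]:
                cols[f"{cov}_{level}"] = (col == level).to_numpy(float)
        elif col.dtype.kind == "b":
            cols[cov] = col.to_numpy(float)
        else:
            cols[cov] = col.to_numpy(float)
    return pd.DataFrame(cols, index=intervals.index)


def _summary_frame(names, params, se) -> pd.DataFrame:
    z = params / se
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "coef": params,
            "hr": np.exp(params),
            "se": se,
            "ci_low": np.exp(params - 1.959963984540054 * se),
            "ci_high": np.exp(params + 1.959963984540054 * se),
            "p": p,
        },
        index=pd.Index(names, name="term"),
    )


def _score_residuals(entry, exit_, status, X, params):
    """Per-interval Cox score residuals (Breslow form), vectorised.

    For interval *i*: ``U_i = d_i (x_i - xbar(t_i)) - w_i * sum over event
    times t_k in (entry_i, exit_i] of (d_k/S0_k) (x_i - xbar(t_k))`` with
    ``w = exp(x beta)``, ``S0/S1`` the weighted risk-set sums and ``xbar =
    S1/S0``.  Identical to the Efron form when event times are untied.
    """
    w = np.exp(X @ params)
    ev = status.astype(bool)
    t_ev, d = np.unique(exit_[ev], return_counts=True)
    # risk-set indicator entry < t <= exit decomposes as 1(exit>=t)-1(entry>=t)
    order_exit = np.argsort(exit_)
    order_entry = np.argsort(entry)
    wx = w[:, None] * X

    def suffix_sums(times_sorted, vals_sorted, at):
        csum = np.concatenate([np.zeros((1,) + vals_sorted.shape[1:]), np.cumsum(vals_sorted, axis=0)])
        total = csum[-1]
        idx = np.searchsorted(times_sorted, at, side="left")
        return total - csum[idx]

    exit_sorted = exit_[order_exit]
    entry_sorted = entry[order_entry]
    S0 = suffix_sums(exit_sorted, w[order_exit, None], t_ev)[:, 0] - suffix_sums(
        entry_sorted, w[order_entry, None], t_ev
    )[:, 0]
    S1 = suffix_sums(exit_sorted, wx[order_exit], t_ev) - suffix_sums(
        entry_sorted, wx[order_entry], t_ev
    )
    xbar = S1 / S0[:, None]
    A = d / S0
    B = xbar * A[:, None]
    cumA = np.concatenate([[0.0], np.cumsum(A)])
    cumB = np.concatenate([np.zeros((1, X.shape[1])), np.cumsum(B, axis=0)])
    hi = np.searchsorted(t_ev, exit_, side="right")
    lo = np.searchsorted(t_ev, entry, side="right")
    sumA = cumA[hi] - cumA[lo]
    sumB = cumB[hi] - cumB[lo]
    U = -w[:, None] * (X * sumA[:, None] - sumB)
    ev_idx = np.searchsorted(t_ev, exit_[ev])
    U[ev] += X[ev] - xbar[ev_idx]
    return U


def cox_fit(
    intervals: pd.DataFrame,
    covariates=None,
    ties: str = "efron",
    cluster: bool = True,
    model_tag: str = "cox",
    time_scale: str | None = None,
) -> RegressionResult:
    """Marginal Cox model on counting-process intervals.

    The partial likelihood is formed over risk sets ``{i: entry_i < u <=
    exit_i}`` (delayed entry handled natively), and with ``cluster=True`` the
    variance is the robust sandwich aggregating score residuals within
    ``cluster_id`` — the marginal model for correlated subjects (same
    hospital, or same matched pair).
    """
    X = _design_matrix(intervals, covariates)
    if X.shape[1] == 0:
        raise ValueError("no covariates to fit")
    const = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    n_events = int(intervals["event"].sum())
    if n_events < 1:
        raise ValueError("need at least one event")
    Xa = X.to_numpy(float)
    entry = intervals["entry"].to_numpy(float)
    exit_ = intervals["exit"].to_numpy(float)
    status = intervals["event"].to_numpy(int)
    model = PHReg(exit_, Xa, status=status, entry=entry, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    params = np.asarray(res.params, float)
    score = model.score(params)
    converged = bool(
        np.all(np.isfinite(params))
        and np.linalg.norm(score) <= 1e-4 * max(1.0, n_events)
    )
    naive_cov = np.asarray(res.cov_params())
    if cluster:
        U = _score_residuals(entry, exit_, status, Xa, params)
        codes, uniques = pd.factorize(intervals["cluster_id"].to_numpy())
        G = np.zeros((len(uniques), Xa.shape[1]))
        np.add.at(G, codes, U)
        cov = naive_cov @ (G.T @ G) @ naive_cov
    else:
        cov = naive_cov
    se = np.sqrt(np.diag(cov))
    return RegressionResult(
        summary=_summary_frame(list(X.columns), params, se),
        n_events=n_events,
        n_intervals=len(intervals),
        converged=converged,
        model_tag=model_tag,
        time_scale=time_scale,
        params=params,
        cov_params=cov,
    )


def cox_two_scale_patient_time(
    cohort: pd.DataFrame, ties: str = "efron", cluster_col: str = "hospital_id"
) -> RegressionResult:
    """Cox model in patient time with the calendar scale as a baseline
    covariate: admission date in years since 1970-01-01 (a fixed, exactly
    rescaled copy of the admission day)."""
    intervals = to_counting_process(
        cohort, scale="patient_time", covariates=("group",), cluster_col=cluster_col
    )
    years = cohort["admission_day"].to_numpy(float) / 365.25
    covs = ["group"]
    if np.ptp(years) == 0:
        warnings.warn(
            "admission day is constant; dropping the calendar covariate",
            stacklevel=2,
        )
    else:
        intervals["admission_years"] = years
        covs.append("admission_years")
    return cox_fit(
        intervals,
        covariates=covs,
        ties=ties,
        model_tag="cox_two_scale",
        time_scale="patient_time",
    )


def weekly_segments(
    cohort: pd.DataFrame,
    update_interval: float = 7.0,
    cluster_col: str = "hospital_id",
) -> pd.DataFrame:
    """Counting-process intervals on the calendar scale with the time-varying
    covariate ``days_since_admission`` held constant within segments of
    ``update_interval`` days (last segment partial)."""
    if update_interval <= 0:
        raise ValueError("update_interval must be positive")
    c_star = cohort["admission_day"].to_numpy(float)
    followup = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(bool)
    n_seg = np.ceil(followup / update_interval).astype(int)
    idx = np.repeat(np.arange(len(cohort)), n_seg)
    seg = np.concatenate([np.arange(k) for k in n_seg]).astype(float)
    t_start = seg * update_interval
    t_stop = np.minimum(t_start + update_interval, followup[idx])
    last = t_stop == followup[idx]
    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy()[idx],
            "entry": c_star[idx] + t_start,
            "exit": c_star[idx] + t_stop,
            "event": event[idx] & last,
            "cluster_id": cohort[cluster_col].to_numpy()[idx],
            "group": cohort["group"].to_numpy()[idx],
            "days_since_admission": t_start,
        }
    )


def cox_two_scale_calendar(
    cohort: pd.DataFrame,
    update_interval: float = 7.0,
    ties: str = "efron",
    cluster_col: str = "hospital_id",
) -> RegressionResult:
    """Cox model in calendar time with time since admission as a time-varying
    covariate, updated every ``update_interval`` days (weekly by default).

    Each subject's follow-up ``(c*, c* + T*]`` is split into consecutive
    segments of the update length (last one partial); within a segment the
    covariate is the days since admission at the segment start.
    """
    intervals = weekly_segments(cohort, update_interval, cluster_col=cluster_col)
    covs = ["group"]
    if np.ptp(intervals["days_since_admission"].to_numpy()) == 0:
        warnings.warn(
            "time since admission is constant across segments; dropping it",
            stacklevel=2,
        )
    else:
        covs.append("days_since_admission")
    return cox_fit(
        intervals,
        covariates=covs,
        ties=ties,
        model_tag="cox_two_scale",
        time_scale="calendar",
    )


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostic (Grambsch-Therneau)
# ---------------------------------------------------------------------------


def _schoenfeld_residuals(intervals, X, params):
    entry = intervals["entry"].to_numpy(float)
    exit_ = intervals["exit"].to_numpy(float)
    event = intervals["event"].to_numpy(bool)
    Xa = X.to_numpy(float)
    eta = np.exp(Xa @ params)
    times = np.unique(exit_[event])
    resid, res_times = [], []
    for u in times:
        at_risk = (entry < u) & (u <= exit_)
        w = eta[at_risk]
        xr = Xa[at_risk]
        xbar = (w[:, None] * xr).sum(axis=0) / w.sum()
        for i in np.flatnonzero(event & (exit_ == u)):
            resid.append(Xa[i] - xbar)
            res_times.append(u)
    return np.asarray(res_times), np.asarray(resid)


def ph_test(
    intervals: pd.DataFrame,
    covariates=None,
    result: RegressionResult | None = None,
    transform: str = "identity",
    ties: str = "efron",
) -> pd.DataFrame:
    """Grambsch–Therneau test of the proportional-hazards assumption.

    Scores the slope of the scaled Schoenfeld residuals against a transform
    ``g(t)`` of the event times (``identity`` or ``rank``); a small p-value
    indicates a time-varying coefficient.  Returns a frame with one row per
    covariate (``chi2``, ``df``, ``p``).  Reproduces the classical score
    statistic of R's ``cox.zph`` (survival < 3.0), including its tendency to
    be conservative under heavy censoring.
    """
    if result is None:
        result = cox_fit(intervals, covariates=covariates, ties=ties, cluster=False)
    if not result.converged:
        raise ValueError("ph_test requires a converged Cox fit")
    X = _design_matrix(intervals, covariates)
    if int(intervals["event"].sum()) < 2:
        raise ValueError("too few events for a proportional-hazards test")
    times, resid = _schoenfeld_residuals(intervals, X, result.params)
    d = len(times)
    if transform == "rank":
        g = scipy.stats.rankdata(times).astype(float)
    elif transform == "identity":
        g = times.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    g = g - g.mean()
    # model-based covariance of beta-hat (not the robust one)
    model = PHReg(
        intervals["exit"].to_numpy(float),
        X.to_numpy(float),
        status=intervals["event"].to_numpy(int),
        entry=intervals["entry"].to_numpy(float),
        ties=ties,
    )
    V = np.linalg.inv(-model.hessian(result.params))
    scaled = resid @ V * d  # scaled Schoenfeld residuals (minus beta-hat)
    num = g @ scaled
    denom = d * np.diag(V) * (g @ g)
    chi2 = num**2 / denom
    p = scipy.stats.chi2.sf(chi2, df=1)
    return pd.DataFrame({"chi2": chi2, "df": 1, "p": p}, index=X.columns)


# ---------------------------------------------------------------------------
# Lexis splitting and Poisson rate regression
# ---------------------------------------------------------------------------


def default_calendar_cuts(cohort: pd.DataFrame) -> np.ndarray:
    """Calendar-year boundaries (Jan 1 epoch days) covering the cohort span."""
    from .data_model import date_to_epoch_day, epoch_day_to_date

    c_lo = float(cohort["admission_day"].min())
    c_hi = float((cohort["admission_day"] + cohort["followup_time"]).max())
    y_lo = epoch_day_to_date(int(np.floor(c_lo))).year
    y_hi = epoch_day_to_date(int(np.ceil(c_hi))).year + 1
    return np.array(
        [date_to_epoch_day(f"{y}-01-01") for y in range(y_lo, y_hi + 1)], float
    )


def lexis_split(
    cohort: pd.DataFrame, t_cuts=DEFAULT_T_CUTS, c_cuts=None
) -> pd.DataFrame:
    """Split each subject's follow-up along both time scales at once.

    The follow-up ``(0, T*]`` in patient time — equivalently ``(c*, c*+T*]``
    in calendar time — is partitioned at every patient-time cut and at every
    calendar cut it crosses; person-time is accumulated and the (single)
    event is assigned to the segment containing the exit.  Segments are then
    aggregated over subjects into cells of group x patient-time band x
    calendar band.  Person-time and event totals are conserved exactly and
    asserted on every call.
    """
    t_cuts = np.asarray(t_cuts, float)
    if t_cuts[0] != 0:
        t_cuts = np.concatenate([[0.0], t_cuts])
    if np.any(np.diff(t_cuts) <= 0):
        raise ValueError("t_cuts must be strictly increasing")
    if c_cuts is None:
        c_cuts = default_calendar_cuts(cohort)
    c_cuts = np.asarray(c_cuts, float)
    if np.any(np.diff(c_cuts) <= 0):
        raise ValueError("c_cuts must be strictly increasing")

    c_star = cohort["admission_day"].to_numpy(float)
    followup = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(bool)
    groups = cohort["group"].to_numpy()

    bad = followup > t_cuts[-1] + 1e-9
    if bad.any():
        sid = cohort["subject_id"].to_numpy()[bad][0]
        raise ValueError(
            f"t_cuts do not cover follow-up of subject {sid!r} "
            f"(T*={followup[bad][0]}, last cut {t_cuts[-1]})"
        )
    bad = (c_star < c_cuts[0]) | (c_star + followup > c_cuts[-1] + 1e-9)
    if bad.any():
        sid = cohort["subject_id"].to_numpy()[bad][0]
        raise ValueError(
            f"c_cuts do not cover calendar span of subject {sid!r}"
        )

    n = len(cohort)
    # candidate segment boundaries in patient time, per subject: the fixed
    # t_cuts plus the calendar cuts shifted by -c*, all clipped to [0, T*]
    cand = np.concatenate(
        [
            np.broadcast_to(t_cuts, (n, len(t_cuts))),
            c_cuts[None, :] - c_star[:, None],
        ],
        axis=1,
    )
    cand = np.clip(cand, 0.0, followup[:, None])
    cand = np.sort(cand, axis=1)
    a = cand[:, :-1]
    b = cand[:, 1:]
    length = b - a
    keep = length > 0
    # the segment ending at T* (the last positive-length one) holds the event
    is_last = keep & (b >= followup[:, None] - 1e-12)

    t_band = np.searchsorted(t_cuts, b, side="left") - 1
    c_band = np.searchsorted(c_cuts, c_star[:, None] + b, side="left") - 1
    group_codes, group_levels = pd.factorize(groups)
    gb = np.broadcast_to(group_codes[:, None], b.shape)

    flat_keep = keep.ravel()
    cell = (
        gb.ravel()[flat_keep] * (len(t_cuts) * len(c_cuts))
        + t_band.ravel()[flat_keep] * len(c_cuts)
        + c_band.ravel()[flat_keep]
    )
    pt = np.bincount(
        cell,
        weights=length.ravel()[flat_keep],
        minlength=len(group_levels) * len(t_cuts) * len(c_cuts),
    )
    ev_weights = (is_last & event[:, None] & keep).ravel()[flat_keep].astype(float)
    ev = np.bincount(cell, weights=ev_weights, minlength=len(pt))

    nz = pt > 0
    codes = np.flatnonzero(nz)
    g_idx = codes // (len(t_cuts) * len(c_cuts))
    t_idx = (codes // len(c_cuts)) % len(t_cuts)
    c_idx = codes % len(c_cuts)
    cells = pd.DataFrame(
        {
            "group": group_levels[g_idx],
            "t_band": t_idx,
            "c_band": c_idx,
            "t_lo": t_cuts[t_idx],
            "t_hi": t_cuts[np.minimum(t_idx + 1, len(t_cuts) - 1)],
            "c_lo": c_cuts[c_idx],
            "c_hi": c_cuts[np.minimum(c_idx + 1, len(c_cuts) - 1)],
            "person_time": pt[nz],
            "events": ev[nz].astype(int),
        }
    )
    assert abs(cells["person_time"].sum() - followup.sum()) < 1e-6 * max(
        1.0, followup.sum()
    ), "person-time not conserved in Lexis split"
    assert cells["events"].sum() == int(event.sum()), "events not conserved"
    return cells


def poisson_two_scale(
    cells: pd.DataFrame, cluster: np.ndarray | None = None
) -> RegressionResult:
    """Piecewise-exponential rate regression on Lexis cells.

    Log-linear Poisson model ``log E[events] = log(person_time) + beta_group
    + gamma_tband + delta_cband`` with reference-coded band factors.  Bands
    with no events anywhere make their coefficient diverge; their cells are
    dropped with a warning.
    """
    cells = cells[cells["person_time"] > 0].copy()
    if int(cells["events"].sum()) < 1:
        raise ValueError("need at least one event")
    for band in ("t_band", "c_band"):
        if cells[band].nunique() <= 1:
            continue
        dead = cells.groupby(band)["events"].sum()
        dead = dead[dead == 0].index
        if len(dead):
            warnings.warn(
                f"dropping {band} value(s) {list(dead)} with zero events",
                stacklevel=2,
            )
            cells = cells[~cells[band].isin(dead)]
    X_parts = []
    levels = [g for g in GROUPS if g in set(cells["group"])] or sorted(
        set(cells["group"])
    )
    names = []
    for level in levels[1:]:
        X_parts.append((cells["group"] == level).to_numpy(float))
        names.append(f"group_{level}")
    for band in ("t_band", "c_band"):
        vals = np.sort(cells[band].unique())
        for v in vals[1:]:
            X_parts.append((cells[band] == v).to_numpy(float))
            names.append(f"{band}_{int(v)}")
    X = np.column_stack([np.ones(len(cells))] + X_parts)
    names = ["intercept"] + names
    model = sm.GLM(
        cells["events"].to_numpy(float),
        X,
        family=sm.families.Poisson(),
        offset=np.log(cells["person_time"].to_numpy(float)),
    )
    if cluster is not None:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
    else:
        res = model.fit()
    params = np.asarray(res.params, float)
    se = np.asarray(res.bse, float)
    return RegressionResult(
        summary=_summary_frame(names, params, se),
        n_events=int(cells["events"].sum()),
        n_intervals=len(cells),
        converged=bool(res.converged),
        model_tag="poisson_two_scale",
        time_scale="both",
        params=params,
        cov_params=np.asarray(res.cov_params()),
    )
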