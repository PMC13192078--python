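"""Seeded synthetic-cohort generator and replication harness.

Emulates the structure of a nationwide hospital-certification study: ~10^2
hospitals certified at dates spread over a multi-year calendar window, ~10^4
patients admitted around their hospital's certification date and classified
Pre / Transitional / Post, a monotonically decreasing hazard after admission,
and purely administrative censoring at 180 days.  Because per-hospital
admissions span a window around certification, Pre admissions precede Post
admissions in calendar time by construction — together with the decreasing
hazard this reproduces the structural bias of the calendar time scale under a
true null effect.

Randomness follows a strict substream contract: the root seed spawns one
:class:`numpy.random.SeedSequence` child per hospital (and per replication in
the harness), so enlarging the simulation never perturbs existing draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_MAX_FOLLOWUP,
    DEFAULT_WINDOW,
    build_cohort,
    date_to_epoch_day,
    epoch_day_to_date,
    to_counting_process,
)
from .hazard_approx import PiecewiseConstantHazard
from .matching import match_one_to_one, matched_cohort
from .regression import (
    DEFAULT_T_CUTS,
    cox_fit,
    cox_two_scale_calendar,
    cox_two_scale_patient_time,
    lexis_split,
    poisson_two_scale,
)


def default_true_hazard() -> PiecewiseConstantHazard:
    """Monotonically decreasing 4-piece hazard over (0, 180] days.

    Rates 7e-3, 2e-3, 8e-4, 4e-4 per day on (0,7], (7,30], (30,90], (90,180]
    give a 180-day cumulative hazard of ~0.18 (~16 % mortality), highest in
    the first week after admission — the typical mortality profile of
    geriatric fracture cohorts.  These are package defaults, not estimates
    from any particular dataset.
    """
    return PiecewiseConstantHazard(
        cut_points=np.array([0.0, 7.0, 30.0, 90.0, 180.0]),
        rates=np.array([0.007, 0.002, 0.0008, 0.0004]),
    )


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the motivating study design: 154 hospitals certified
    uniformly over 2013-2021, ~192 patients each (~29 600 total), admissions
    drawn uniformly over the whole observation window for every hospital (a
    claims cohort observes each hospital throughout the study period), 180-day
    administrative censoring, and no group effect (all multipliers 1).

    ``admission_window`` is the absolute calendar window admissions are drawn
    from (defaults to the certification window).  Setting
    ``admission_offset_window`` instead draws admissions relative to each
    hospital's certification day and takes precedence when given.
    """

    n_hospitals: int = 154
    certification_window: tuple[int, int] = (
        date_to_epoch_day("2013-01-01"),
        date_to_epoch_day("2021-12-31"),
    )
    patients_per_hospital: int = 192
    admission_window: tuple[int, int] | None = None
    admission_offset_window: tuple[int, int] | None = None
    true_hazard: PiecewiseConstantHazard = field(default_factory=default_true_hazard)
    group_multipliers: dict = field(
        default_factory=lambda: {"Pre": 1.0, "Transitional": 1.0, "Post": 1.0}
    )
    group_window: int = DEFAULT_WINDOW
    max_followup: float = DEFAULT_MAX_FOLLOWUP
    extra_censoring_rate: float = 0.0
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self):
        lo, hi = self.certification_window
        if hi < lo:
            raise ValueError("empty certification window")
        if self.admission_window is None and self.admission_offset_window is None:
            self.admission_window = self.certification_window
        for win in (self.admission_window, self.admission_offset_window):
            if win is not None and win[1] < win[0]:
                raise ValueError("empty admission window")
        if any(m <= 0 for m in self.group_multipliers.values()):
            raise ValueError("group multipliers must be positive")


def sample_event_time(pwh: PiecewiseConstantHazard, multiplier: float, u):
    """Invert ``multiplier * A(t) = -log(u)`` for uniform draws ``u``.

    Solved interval-by-interval in closed form; returns ``inf`` where the
    target exceeds the total cumulative hazard (the event never occurs within
    the hazard's support).
    """
    u_arr = np.atleast_1d(np.asarray(u, float))
    if np.any((u_arr <= 0) | (u_arr >= 1)):
        raise ValueError("u must lie strictly in (0, 1)")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    target = -np.log(u_arr) / multiplier
    widths = np.diff(pwh.cut_points)
    cum = np.concatenate([[0.0], np.cumsum(pwh.rates * widths)])
    out = np.full(len(u_arr), np.inf)
    k = np.searchsorted(cum, target, side="left")  # first cut with A >= target
    inside = k <= len(pwh.rates)
    ki = k[inside]
    # target falls in interval ki-1 -> ki; rate there is positive because the
    # cumulative hazard strictly increases across it
    ki = np.maximum(ki, 1)
    out[inside] = pwh.cut_points[ki - 1] + (
        target[inside] - cum[ki - 1]
    ) / pwh.rates[ki - 1]
    return out if np.ndim(u) else float(out[0])


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate subjects and hospitals tables (the CSV dialects of the
    cohort builder) from a :class:`SimulationConfig`.

    Per hospital: a certification day uniform in the certification window;
    admissions uniform in the offset window around it; event times by inverse
    transform from the true hazard scaled by the admitted patient's group
    multiplier; administrative censoring at ``max_followup`` plus optional
    independent exponential censoring.  Byte-identical output for a given
    seed.
    """
    ss = (
        config.seed
        if isinstance(config.seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed)
    )
    children = ss.spawn(config.n_hospitals)
    cert_lo, cert_hi = config.certification_window
    mult = config.group_multipliers
    hosp_rows = []
    subj_frames = []
    for h, child in enumerate(children):
        rng = np.random.default_rng(child)
        hospital_id = f"H{h:03d}"
        cert = int(rng.integers(cert_lo, cert_hi + 1))
        m = int(config.patients_per_hospital)
        if config.admission_offset_window is not None:
            off_lo, off_hi = config.admission_offset_window
            admission = cert + rng.integers(off_lo, off_hi + 1, size=m)
        else:
            adm_lo, adm_hi = config.admission_window
            admission = rng.integers(adm_lo, adm_hi + 1, size=m)
        dist = admission - cert
        group = np.where(
            dist <= -config.group_window,
            "Pre",
            np.where(dist >= config.group_window, "Post", "Transitional"),
        )
        u = rng.uniform(size=m)
        t_event = np.empty(m)
        for g in np.unique(group):
            sel = group == g
            t_event[sel] = sample_event_time(config.true_hazard, mult[g], u[sel])
        censor = np.full(m, float(config.max_followup))
        if config.extra_censoring_rate > 0:
            censor = np.minimum(
                censor, rng.exponential(1.0 / config.extra_censoring_rate, size=m)
            )
        followup = np.minimum(t_event, censor)
        event = t_event <= censor
        subj_frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{hospital_id}P{j:04d}" for j in range(m)],
                    "hospital_id": hospital_id,
                    "admission_date": [
                        epoch_day_to_date(a).isoformat() for a in admission
                    ],
                    "admission_day": admission.astype(int),
                    "followup_days": followup,
                    "event": event.astype(int),
                }
            )
        )
        hosp_rows.append(
            (hospital_id, epoch_day_to_date(cert).isoformat(), cert)
        )
    subjects = pd.concat(subj_frames, ignore_index=True)
    hospitals = pd.DataFrame(
        hosp_rows, columns=["hospital_id", "certification_date", "certification_day"]
    )
    return subjects, hospitals


def bias_config(**overrides) -> SimulationConfig:
    """The canonical structural-bias preset: null group effect, decreasing
    hazard, and Pre admissions preceding Post admissions within each hospital
    (all of which hold for the defaults; overrides adjust scale etc.)."""
    return SimulationConfig(**overrides)


def bias_scenario(**overrides) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate subjects/hospitals tables from the canonical bias preset."""
    return simulate_cohort(bias_config(**overrides))


def cohort_from_config(config: SimulationConfig) -> pd.DataFrame:
    """Simulate and immediately build the analysis cohort."""
    subjects, hospitals = simulate_cohort(config)
    return build_cohort(
        subjects,
        hospitals,
        window=config.group_window,
        max_followup=config.max_followup,
    )


# ---------------------------------------------------------------------------
# Replication harness
# ---------------------------------------------------------------------------

ALL_METHODS = (
    "cox_calendar",
    "cox_patient_time",
    "cox_matched_patient_time",
    "cox_matched_calendar",
    "cox_two_scale_patient",
    "cox_two_scale_calendar",
    "poisson_two_scale",
)


def _fit_method(method: str, cohort: pd.DataFrame, match_seed: int, t_cuts):
    if method == "cox_calendar":
        return cox_fit(
            to_counting_process(cohort, "calendar"),
            model_tag="cox_naive",
            time_scale="calendar",
        )
    if method == "cox_patient_time":
        return cox_fit(
            to_counting_process(cohort, "patient_time"),
            model_tag="cox",
            time_scale="patient_time",
        )
    if method in ("cox_matched_patient_time", "cox_matched_calendar"):
        pairs, _ = match_one_to_one(cohort, seed=match_seed)
        if len(pairs) == 0:
            raise ValueError("no matched pairs")
        sub = matched_cohort(pairs, cohort)
        scale = "patient_time" if method.endswith("patient_time") else "calendar"
        return cox_fit(
            to_counting_process(sub, scale, cluster_col="pair_id"),
            model_tag="cox_matched",
            time_scale=scale,
        )
    if method == "cox_two_scale_patient":
        return cox_two_scale_patient_time(cohort)
    if method == "cox_two_scale_calendar":
        return cox_two_scale_calendar(cohort)
    if method == "poisson_two_scale":
        cells = lexis_split(cohort, t_cuts=t_cuts)
        return poisson_two_scale(cells)
    raise ValueError(f"unknown method {method!r}")


def replicate_experiment(
    config: SimulationConfig,
    n_reps: int,
    methods=ALL_METHODS,
    true_hr: float = 1.0,
    term: str = "group_Post",
    t_cuts=DEFAULT_T_CUTS,
    keep_replicates: bool = False,
):
    """Fit the requested estimators on ``n_reps`` independent cohorts.

    Reports, per method, the mean and SD of the log hazard-ratio estimates of
    ``term``, the geometric-mean HR, and the fraction of 95 % CIs covering
    ``true_hr``.  Non-converged or failed fits are recorded and excluded from
    the averages, never fatal.  Each replication draws from its own spawned
    substream of the config seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = (
        config.seed
        if isinstance(config.seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed)
    )
    rep_seeds = root.spawn(n_reps)
    records = []
    for r, rep_ss in enumerate(rep_seeds):
        cohort = cohort_from_config(dataclasses.replace(config, seed=rep_ss))
        match_seed = int(rep_ss.generate_state(1)[0] % (2**31))
        for method in methods:
            try:
                res = _fit_method(method, cohort, match_seed, t_cuts)
                lo, hi = res.ci95(term)
                records.append(
                    {
                        "rep": r,
                        "method": method,
                        "loghr": res.coef(term),
                        "se": float(res.summary.loc[term, "se"]),
                        "ci_low": lo,
                        "ci_high": hi,
                        "covered": bool(lo <= true_hr <= hi),
                        "converged": res.converged,
                    }
                )
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                records.append(
                    {
                        "rep": r,
                        "method": method,
                        "loghr": np.nan,
                        "se": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "covered": False,
                        "converged": False,
                        "error": str(exc),
                    }
                )
    replicates = pd.DataFrame(records)
    ok = replicates[replicates["converged"]]
    summary = (
        ok.groupby("method")
        .agg(
            mean_loghr=("loghr", "mean"),
            sd_loghr=("loghr", "std"),
            coverage=("covered", "mean"),
            n_ok=("loghr", "size"),
        )
        .reindex(list(methods))
    )
    summary["mean_hr"] = np.exp(summary["mean_loghr"])
    summary["n_failed"] = n_reps - summary["n_ok"].fillna(0).astype(int)
    if keep_replicates:
        return summary, replicates
    return summary
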