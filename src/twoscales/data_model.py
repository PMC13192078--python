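"""Cohort construction: calendar conventions, certification groups, counting processes.

Two time scales are used throughout the package:

* **patient time** ``t`` — days since the subject's hospital admission; every
  subject is under observation from ``t = 0``, so no delayed entry occurs.
* **calendar time** ``c`` — days since 1970-01-01 (the epoch).  Subjects enter
  the risk set at their admission day ``c*``, i.e. they are left-truncated.

A cohort is a :class:`pandas.DataFrame` with one row per subject and columns
``subject_id, hospital_id, admission_day, followup_time, event, group``
(the ``SubjectRecord`` layout).  Counting-process interval sets are DataFrames
with columns ``subject_id, entry, exit, event, cluster_id`` plus covariate
columns; throughout the package a subject is at risk at time ``u`` iff
``entry < u <= exit``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

EPOCH = _dt.date(1970, 1, 1)

#: Certification group labels, in temporal order of admission.
GROUPS = ("Pre", "Transitional", "Post")

#: Default half-width (days) of the transitional window around certification.
DEFAULT_WINDOW = 180

#: Default administrative censoring horizon (days after admission).
DEFAULT_MAX_FOLLOWUP = 180.0

SUBJECT_COLUMNS = [
    "subject_id",
    "hospital_id",
    "admission_day",
    "followup_time",
    "event",
    "group",
]

INTERVAL_COLUMNS = ["subject_id", "entry", "exit", "event", "cluster_id"]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: admission day ``c*``, observed time ``T*``, event status."""

    subject_id: str
    hospital_id: str
    admission_day: float
    followup_time: float
    event: bool
    group: str


@dataclass(frozen=True)
class HospitalRecord:
    hospital_id: str
    certification_day: int


def date_to_epoch_day(date) -> int:
    """Convert a Gregorian date (``datetime.date`` or ISO-8601 string) to days
    since 1970-01-01.

    1970-01-01 maps to 0; e.g. 2015-01-01 maps to 16436.  Dates before the
    epoch are outside the study scope and rejected.
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    elif isinstance(date, _dt.datetime):
        date = date.date()
    if not isinstance(date, _dt.date):
        raise TypeError(f"expected a date or ISO-8601 string, got {type(date)!r}")
    day = (date - EPOCH).days
    if day < 0:
        raise ValueError(f"date {date} precedes the 1970-01-01 origin")
    return day


def epoch_day_to_date(day: int) -> _dt.date:
    """Inverse of :func:`date_to_epoch_day` for integer epoch days."""
    return EPOCH + _dt.timedelta(days=int(day))


def assign_group(admission_day, certification_day, window: int = DEFAULT_WINDOW) -> str:
    """Classify an admission relative to the hospital's certification date.

    ``Pre``          admission_day <= certification_day - window
    ``Transitional`` strictly between the two bounds
    ``Post``         admission_day >= certification_day + window

    The closed bounds make the three phases strictly separated: admissions
    exactly ``window`` days before (after) certification count as Pre (Post).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if admission_day <= certification_day - window:
        return "Pre"
    if admission_day >= certification_day + window:
        return "Post"
    return "Transitional"


def _as_frame(table, columns: Iterable[str], name: str) -> pd.DataFrame:
    df = pd.DataFrame(table)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing columns {missing}")
    return df


def build_cohort(
    subjects,
    hospitals,
    window: int = DEFAULT_WINDOW,
    max_followup: float = DEFAULT_MAX_FOLLOWUP,
) -> pd.DataFrame:
    """Assemble the analysis cohort from subject and hospital tables.

    ``subjects`` needs columns ``subject_id, hospital_id, admission_day,
    followup_time, event`` (or ``admission_date`` / ``followup_days`` aliases
    as read from CSV); ``hospitals`` needs ``hospital_id, certification_day``.

    Applies administrative censoring: any follow-up beyond ``max_followup``
    is cut back to ``max_followup`` with the event flag cleared, so every
    downstream module sees one consistently censored cohort.
    """
    subjects = pd.DataFrame(subjects).copy()
    if "admission_day" not in subjects.columns and "admission_date" in subjects.columns:
        subjects["admission_day"] = [
            date_to_epoch_day(d) for d in subjects["admission_date"]
        ]
    if "followup_time" not in subjects.columns and "followup_days" in subjects.columns:
        subjects["followup_time"] = subjects["followup_days"]
    subjects = _as_frame(
        subjects,
        ["subject_id", "hospital_id", "admission_day", "followup_time", "event"],
        "subjects",
    )
    hospitals = pd.DataFrame(hospitals).copy()
    if (
        "certification_day" not in hospitals.columns
        and "certification_date" in hospitals.columns
    ):
        hospitals["certification_day"] = [
            date_to_epoch_day(d) for d in hospitals["certification_date"]
        ]
    hospitals = _as_frame(hospitals, ["hospital_id", "certification_day"], "hospitals")

    bad = subjects.loc[subjects["followup_time"] <= 0, "subject_id"].tolist()
    if bad:
        raise ValueError(f"non-positive follow-up time for subjects {bad}")

    cert = hospitals.set_index("hospital_id")["certification_day"]
    if cert.index.has_duplicates:
        raise ValueError("duplicate hospital_id in hospitals table")
    orphan = subjects.loc[~subjects["hospital_id"].isin(cert.index), "subject_id"]
    if len(orphan):
        raise ValueError(
            f"subjects with unknown hospital_id: {orphan.tolist()}"
        )

    cohort = subjects.copy()
    cohort["admission_day"] = cohort["admission_day"].astype(float)
    cohort["followup_time"] = cohort["followup_time"].astype(float)
    cohort["event"] = cohort["event"].astype(bool)
    over = cohort["followup_time"] > max_followup
    cohort.loc[over, "followup_time"] = float(max_followup)
    cohort.loc[over, "event"] = False
    cert_days = cohort["hospital_id"].map(cert)
    cohort["group"] = [
        assign_group(a, cd, window)
        for a, cd in zip(cohort["admission_day"], cert_days)
    ]
    return cohort[SUBJECT_COLUMNS].reset_index(drop=True)


def to_counting_process(
    cohort: pd.DataFrame,
    scale: str = "patient_time",
    covariates: Iterable[str] = ("group",),
    cluster_col: str = "hospital_id",
) -> pd.DataFrame:
    """Represent a cohort as counting-process intervals on the chosen scale.

    ``patient_time`` gives ``(entry, exit) = (0, T*)`` — a common time zero —
    while ``calendar`` gives ``(c*, c* + T*)``, i.e. left-truncated entries.
    ``cluster_id`` carries the clustering unit for marginal (sandwich) models.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if scale == "patient_time":
        entry = np.zeros(len(cohort))
        exit_ = cohort["followup_time"].to_numpy(float)
    elif scale == "calendar":
        entry = cohort["admission_day"].to_numpy(float)
        exit_ = entry + cohort["followup_time"].to_numpy(float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    out = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "entry": entry,
            "exit": exit_,
            "event": cohort["event"].to_numpy(bool),
            "cluster_id": cohort[cluster_col].to_numpy(),
        }
    )
    for cov in covariates:
        out[cov] = cohort[cov].to_numpy()
    return out


def read_subjects(path) -> pd.DataFrame:
    """Read the subjects CSV dialect
    (``subject_id,hospital_id,admission_date,followup_days,event``)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "hospital_id": str})
    required = {"subject_id", "hospital_id", "admission_date", "followup_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subjects CSV missing columns {sorted(missing)}")
    df["admission_day"] = [date_to_epoch_day(d) for d in df["admission_date"]]
    df["followup_time"] = df["followup_days"].astype(float)
    df["event"] = df["event"].astype(int).astype(bool)
    return df


def read_hospitals(path) -> pd.DataFrame:
    """Read the hospitals CSV dialect (``hospital_id,certification_date``)."""
    df = pd.read_csv(path, dtype={"hospital_id": str})
    required = {"hospital_id", "certification_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hospitals CSV missing columns {sorted(missing)}")
    df["certification_day"] = [date_to_epoch_day(d) for d in df["certification_date"]]
    return df
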