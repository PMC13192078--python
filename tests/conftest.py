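import numpy as np
import pandas as pd
import pytest

import twoscales as ts


def intervals_frame(entries, exits, events, covs=None, clusters=None):
    """Assemble a counting-process interval frame from plain sequences."""
    n = len(exits)
    out = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "entry": np.asarray(entries, float),
            "exit": np.asarray(exits, float),
            "event": np.asarray(events, bool),
            "cluster_id": clusters if clusters is not None else [f"s{i}" for i in range(n)],
        }
    )
    if covs is not None:
        for name, vals in covs.items():
            out[name] = vals
    return out


def random_intervals(rng, n, with_entry=False):
    entry = rng.uniform(0, 3, n) if with_entry else np.zeros(n)
    dur = rng.exponential(5, n) + 1e-3
    exit_ = entry + dur
    event = rng.uniform(size=n) < 0.7
    return intervals_frame(entry, exit_, event)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    cfg = ts.bias_config(n_hospitals=12, patients_per_hospital=60, seed=2024)
    return ts.cohort_from_config(cfg)


@pytest.fixture()
def toy_tables():
    subjects = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c"],
            "hospital_id": ["h1", "h1", "h1"],
            "admission_day": [16000, 16436, 16700],
            "followup_time": [30.0, 14.0, 200.0],
            "event": [True, True, True],
        }
    )
    hospitals = pd.DataFrame({"hospital_id": ["h1"], "certification_day": [16436]})
    return subjects, hospitals
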