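import numpy as np
import pandas as pd
import pytest

import twoscales as ts
from twoscales.regression import ph_test, weekly_segments
from conftest import intervals_frame


def grid_search_cox_oracle(intervals, beta_grid):
    """Maximise the written-out partial likelihood over a dense beta grid.

    Valid for a single binary covariate and untied event times; risk sets use
    the entry < u <= exit convention, so delayed entry is respected.
    """
    entry = intervals["entry"].to_numpy(float)
    exit_ = intervals["exit"].to_numpy(float)
    event = intervals["event"].to_numpy(bool)
    x = intervals["x"].to_numpy(float)
    loglik = np.zeros_like(beta_grid)
    for u in exit_[event]:
        at_risk = (entry < u) & (u <= exit_)
        xi = x[event & (exit_ == u)][0]
        loglik += beta_grid * xi - np.log(
            np.exp(beta_grid[:, None] * x[at_risk][None, :]).sum(axis=1)
        )
    return beta_grid[np.argmax(loglik)]


def irls_poisson_oracle(y, X, offset, tol=1e-12, max_iter=100):
    """Iteratively reweighted least squares for the Poisson log-linear model,
    coded from the likelihood equations."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = np.exp(X @ beta + offset)
        W = mu
        z = X @ beta + (y - mu) / mu
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


class TestCoxFit:
    def test_symmetric_groups_give_zero_coefficient(self):
        """Identical event/censoring pattern in both groups: label swap is a
        symmetry of the partial likelihood, so the MLE is exactly 0."""
        iv = intervals_frame(
            [0] * 6,
            [2, 4, 6, 2, 4, 6],
            [True, True, False, True, True, False],
            covs={"x": [0, 0, 0, 1, 1, 1]},
        )
        for ties in ("efron", "breslow"):
            res = ts.cox_fit(iv, covariates=["x"], ties=ties)
            assert abs(res.coef("x")) < 1e-6

    @pytest.mark.parametrize("with_entry", [False, True])
    def test_matches_grid_search_oracle(self, with_entry):
        rng = np.random.default_rng(5)
        entries = rng.uniform(0, 1, 6) if with_entry else np.zeros(6)
        iv = intervals_frame(
            entries,
            entries + np.array([1.1, 2.3, 3.7, 1.9, 2.9, 4.3]),
            [True, True, True, True, True, False],
            covs={"x": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]},
        )
        beta_grid = np.linspace(-5, 5, 200_001)
        oracle = grid_search_cox_oracle(iv, beta_grid)
        res = ts.cox_fit(iv, covariates=["x"])
        assert res.converged
        assert abs(res.coef("x") - oracle) < 1e-3

    def test_singleton_clusters_equal_unclustered_sandwich(self):
        """With every subject its own cluster the robust variance must agree
        with an established unclustered-sandwich implementation."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        n = 80
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(8 / np.exp(0.4 * x))
        ev = t <= 12
        t = np.minimum(t, 12)
        iv = intervals_frame(np.zeros(n), t, ev, covs={"x": x})
        res = ts.cox_fit(iv, covariates=["x"])
        cph = lifelines.CoxPHFitter()
        cph.fit(
            pd.DataFrame({"T": t, "E": ev.astype(int), "x": x}),
            duration_col="T",
            event_col="E",
            robust=True,
        )
        assert res.coef("x") == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)
        assert float(res.summary.loc["x", "se"]) == pytest.approx(
            float(cph.standard_errors_.iloc[0]), rel=1e-5
        )

    def test_constant_covariate_rejected(self):
        iv = intervals_frame([0, 0], [1, 2], [True, True], covs={"x": [1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            ts.cox_fit(iv, covariates=["x"])

    def test_no_events_rejected(self):
        iv = intervals_frame([0, 0], [1, 2], [False, False], covs={"x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="event"):
            ts.cox_fit(iv, covariates=["x"])

    def test_ci_is_exp_of_coef_pm_1959_se(self, small_cohort):
        res = ts.cox_fit(ts.to_counting_process(small_cohort, "patient_time"))
        row = res.summary.loc["group_Post"]
        assert row["ci_low"] == pytest.approx(
            np.exp(row["coef"] - 1.96 * row["se"]), rel=1e-3
        )
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))


class TestTwoScaleCox:
    def test_patient_time_equals_augmented_cox_fit(self, small_cohort):
        res = ts.cox_two_scale_patient_time(small_cohort)
        iv = ts.to_counting_process(small_cohort, "patient_time")
        iv["admission_years"] = small_cohort["admission_day"].to_numpy() / 365.25
        direct = ts.cox_fit(iv, covariates=["group", "admission_years"])
        pd.testing.assert_frame_equal(res.summary, direct.summary)

    def test_constant_admission_drops_calendar_covariate(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["admission_day"] = 16436.0
        cohort["group"] = np.where(np.arange(len(cohort)) % 2 == 0, "Pre", "Post")
        with pytest.warns(UserWarning, match="constant"):
            res = ts.cox_two_scale_patient_time(cohort)
        assert "admission_years" not in res.summary.index

    @pytest.mark.parametrize(
        "followup,exits,covs",
        [
            (14.0, [7.0, 14.0], [0.0, 7.0]),
            (10.0, [7.0, 10.0], [0.0, 7.0]),
            (6.0, [6.0], [0.0]),
        ],
    )
    def test_weekly_segmentation(self, followup, exits, covs):
        cohort = pd.DataFrame(
            {
                "subject_id": ["a"],
                "hospital_id": ["h0"],
                "admission_day": [16436.0],
                "followup_time": [followup],
                "event": [True],
                "group": ["Pre"],
            }
        )
        seg = weekly_segments(cohort, 7.0)
        np.testing.assert_allclose(seg["exit"] - 16436.0, exits)
        np.testing.assert_allclose(seg["days_since_admission"], covs)
        np.testing.assert_allclose(seg["entry"].iloc[0], 16436.0)
        # only the last segment carries the event; segments are contiguous
        assert list(seg["event"]) == [False] * (len(exits) - 1) + [True]
        np.testing.assert_allclose(seg["entry"].iloc[1:], seg["exit"].iloc[:-1])

    def test_large_update_interval_reduces_to_one_scale(self, small_cohort):
        with pytest.warns(UserWarning, match="constant"):
            res = ts.cox_two_scale_calendar(small_cohort, update_interval=1000.0)
        direct = ts.cox_fit(ts.to_counting_process(small_cohort, "calendar"))
        assert res.coef("group_Post") == pytest.approx(
            direct.coef("group_Post"), abs=1e-8
        )


class TestProportionalHazardsTest:
    def test_size_near_nominal_under_proportional_hazards(self):
        rejections = 0
        reps = 120
        for s in range(reps):
            rng = np.random.default_rng(30_000 + s)
            n = 200
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(10, n)
            iv = intervals_frame(np.zeros(n), t, np.ones(n, bool), covs={"x": x})
            p = ph_test(iv, covariates=["x"]).loc["x", "p"]
            rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.11

    def test_power_under_crossing_hazards(self):
        rejections = 0
        reps = 20
        for s in range(reps):
            rng = np.random.default_rng(20_000 + s)
            n = 300
            x = rng.integers(0, 2, n).astype(float)
            t = np.where(x > 0, rng.weibull(3.0, n) * 12, rng.weibull(0.5, n) * 8)
            t = np.maximum(np.minimum(t, 25.0), 1e-3)
            iv = intervals_frame(
                np.zeros(n), t, t < 25.0, covs={"x": x}
            )
            p = ph_test(iv, covariates=["x"]).loc["x", "p"]
            rejections += p < 0.05
        assert rejections / reps > 0.8

    def test_single_event_rejected(self):
        iv = intervals_frame([0, 0], [1, 2], [True, False], covs={"x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            ph_test(iv, covariates=["x"])


class TestLexisSplit:
    def test_hand_partition(self):
        cohort = pd.DataFrame(
            {
                "subject_id": ["a"],
                "hospital_id": ["h0"],
                "admission_day": [16400.0],
                "followup_time": [100.0],
                "event": [True],
                "group": ["Pre"],
            }
        )
        cells = ts.lexis_split(
            cohort, t_cuts=[0, 7, 30, 90, 180], c_cuts=[16300, 16436, 16600]
        )
        before = cells[cells["c_band"] == 0]
        after = cells[cells["c_band"] == 1]
        assert before["person_time"].sum() == pytest.approx(36.0)
        assert after["person_time"].sum() == pytest.approx(64.0)
        np.testing.assert_allclose(
            before.sort_values("t_band")["person_time"], [7.0, 23.0, 6.0]
        )
        np.testing.assert_allclose(
            after.sort_values("t_band")["person_time"], [54.0, 10.0]
        )
        # event lands in the cell containing the exit (t=100, band (90,180])
        assert after.loc[after["t_band"] == 4 - 1, "events"].sum() == 1

    def test_single_band_single_cell(self):
        cohort = pd.DataFrame(
            {
                "subject_id": ["a"],
                "hospital_id": ["h0"],
                "admission_day": [100.0],
                "followup_time": [50.0],
                "event": [True],
                "group": ["Pre"],
            }
        )
        cells = ts.lexis_split(cohort, t_cuts=[0, 180], c_cuts=[0, 1000])
        assert len(cells) == 1
        assert cells.iloc[0]["person_time"] == 50.0
        assert cells.iloc[0]["events"] == 1

    def test_totals_conserved_on_simulated_cohort(self, small_cohort):
        cells = ts.lexis_split(small_cohort)
        assert cells["person_time"].sum() == pytest.approx(
            small_cohort["followup_time"].sum()
        )
        assert cells["events"].sum() == small_cohort["event"].sum()

    def test_uncovering_cuts_name_subject(self):
        cohort = pd.DataFrame(
            {
                "subject_id": ["long_one"],
                "hospital_id": ["h0"],
                "admission_day": [100.0],
                "followup_time": [300.0],
                "event": [False],
                "group": ["Pre"],
            }
        )
        with pytest.raises(ValueError, match="long_one"):
            ts.lexis_split(cohort, t_cuts=[0, 180], c_cuts=[0, 1000])


class TestPoissonTwoScale:
    def test_saturated_closed_form_rate_ratio(self):
        cells = pd.DataFrame(
            {
                "group": ["Pre", "Post"],
                "t_band": [0, 0],
                "c_band": [0, 0],
                "person_time": [100.0, 100.0],
                "events": [1, 2],
            }
        )
        res = ts.poisson_two_scale(cells)
        assert res.hazard_ratio("group_Post") == pytest.approx(2.0, rel=1e-8)

    def test_matches_irls_oracle(self, small_cohort):
        cells = ts.lexis_split(small_cohort)
        res = ts.poisson_two_scale(cells)
        # rebuild the same design and solve independently
        kept = cells[cells["person_time"] > 0].copy()
        for band in ("t_band", "c_band"):
            dead = kept.groupby(band)["events"].sum()
            kept = kept[~kept[band].isin(dead[dead == 0].index)]
        cols = [np.ones(len(kept))]
        for level in ["Transitional", "Post"]:
            cols.append((kept["group"] == level).to_numpy(float))
        for band in ("t_band", "c_band"):
            for v in np.sort(kept[band].unique())[1:]:
                cols.append((kept[band] == v).to_numpy(float))
        X = np.column_stack(cols)
        beta = irls_poisson_oracle(
            kept["events"].to_numpy(float),
            X,
            np.log(kept["person_time"].to_numpy(float)),
        )
        np.testing.assert_allclose(res.params, beta, atol=1e-6)

    def test_one_scale_model_reconstructs_occurrence_exposure(self):
        """Saturated single-group, single-calendar-band Poisson model equals
        the occurrence/exposure rates analytically."""
        cfg = ts.bias_config(n_hospitals=4, patients_per_hospital=80, seed=31)
        cohort = ts.cohort_from_config(cfg)
        cohort = cohort[cohort["group"] == "Pre"].reset_index(drop=True)
        span = (
            float(cohort["admission_day"].min()) - 1,
            float((cohort["admission_day"] + cohort["followup_time"]).max()) + 1,
        )
        cells = ts.lexis_split(cohort, c_cuts=span)
        res = ts.poisson_two_scale(cells)
        iv = ts.to_counting_process(cohort, "patient_time")
        oe = ts.fit_piecewise_hazard(iv, ts.DEFAULT_T_CUTS)
        kept_bands = sorted(cells[cells["events"] > 0]["t_band"].unique())
        base = res.coef("intercept")
        fitted = [np.exp(base)]
        for b in kept_bands[1:]:
            fitted.append(np.exp(base + res.coef(f"t_band_{b}")))
        np.testing.assert_allclose(fitted, oe.rates[kept_bands], rtol=1e-6)

    def test_zero_event_band_dropped_with_warning(self):
        cells = pd.DataFrame(
            {
                "group": ["Pre", "Post", "Pre", "Post"],
                "t_band": [0, 0, 1, 1],
                "c_band": [0, 0, 0, 0],
                "person_time": [100.0, 100.0, 50.0, 50.0],
                "events": [2, 3, 0, 0],
            }
        )
        with pytest.warns(UserWarning, match="t_band"):
            res = ts.poisson_two_scale(cells)
        assert res.n_events == 5


class TestCalendarShiftInvariance:
    def test_patient_time_and_poisson_unchanged_by_calendar_shift(self, small_cohort):
        delta = 3650.0
        shifted = small_cohort.copy()
        shifted["admission_day"] += delta
        res_a = ts.cox_fit(ts.to_counting_process(small_cohort, "patient_time"))
        res_b = ts.cox_fit(ts.to_counting_process(shifted, "patient_time"))
        pd.testing.assert_frame_equal(res_a.summary, res_b.summary)
        c_cuts = ts.default_calendar_cuts(small_cohort)
        cells_a = ts.lexis_split(small_cohort, c_cuts=c_cuts)
        cells_b = ts.lexis_split(shifted, c_cuts=c_cuts + delta)
        ra = ts.poisson_two_scale(cells_a)
        rb = ts.poisson_two_scale(cells_b)
        assert ra.coef("group_Post") == pytest.approx(rb.coef("group_Post"), abs=1e-9)
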