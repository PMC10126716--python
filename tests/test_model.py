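"""Tests for design building, the REML AR(1) estimator, the study model
grid, and the a-priori power computation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from oracles import dense_reml_loglik

from pulsepanel.model import (
    ModelFrame,
    ModelSpec,
    fit_lmm_ar1,
    make_model_frame,
    reml_loglik,
    required_sample_size,
    run_study_models,
)
from pulsepanel.simulate import SimulationConfig, generate_panel


def tiny_panel():
    """Three participants, consecutive days, no covariates beyond exposure."""
    rows = []
    rng = np.random.default_rng(0)
    for pid in ("A", "B", "C"):
        for d in range(6):
            rows.append(
                {
                    "participant_id": pid,
                    "date": dt.date(2017, 3, 1) + dt.timedelta(days=d),
                    "y": rng.normal(60, 3),
                    "x": float(rng.integers(0, 10)),
                }
            )
    return pd.DataFrame(rows)


def simple_spec(lags=(0, 1, 2)):
    return ModelSpec("y", ("x",), lags, adjust=(), month_dummies=False)


class TestMakeModelFrame:
    def test_consecutive_days_keep_all_lags(self):
        panel = tiny_panel()
        frame = make_model_frame(panel, simple_spec())
        # first two days per participant lack lag-1/2 values
        assert len(frame.data) == 3 * 4
        d2 = panel.set_index(["participant_id", "date"])
        row = frame.data.iloc[0]
        date = row["date"]
        for lag in (0, 1, 2):
            want = d2.loc[(row["participant_id"], date - dt.timedelta(days=lag)), "x"]
            assert row[f"x_lag{lag}"] == want

    def test_missing_previous_day_drops_distributed_but_not_single_lag2(self):
        panel = tiny_panel()
        mask = (panel["participant_id"] == "A") & (
            panel["date"] == dt.date(2017, 3, 3)
        )
        panel.loc[mask, "x"] = np.nan
        dlag = make_model_frame(panel, simple_spec())
        a_days = dlag.data[dlag.data["participant_id"] == "A"]["date"].tolist()
        # 3 Mar exposure missing: 3, 4, 5 Mar rows all lose a lag
        assert dt.date(2017, 3, 4) not in a_days and dt.date(2017, 3, 5) not in a_days
        single2 = make_model_frame(panel, simple_spec(lags=(2,)))
        a2 = single2.data[single2.data["participant_id"] == "A"]["date"].tolist()
        assert dt.date(2017, 3, 4) in a2  # lag-2 source (2 Mar) is present

    def test_absent_column_raises(self):
        with pytest.raises(ValueError, match="absent"):
            make_model_frame(tiny_panel(), ModelSpec("y", ("nope",), (0,), adjust=()))

    def test_lags_match_generator_panel_shift(self):
        cfg = SimulationConfig(n_participants=5, days_per_participant=15, seed=21,
                               diary_missing_prob=0.0)
        panel, _ = generate_panel(cfg)
        spec = ModelSpec("resting_hr", ("symptom_score",))
        frame = make_model_frame(panel, spec)
        # independent check via groupwise shift on consecutive days
        chk = panel.sort_values(["participant_id", "date"]).copy()
        for lag in (0, 1, 2):
            chk[f"want_lag{lag}"] = chk.groupby("participant_id")["symptom_score"].shift(lag)
        merged = frame.data.merge(
            chk[["participant_id", "date"] + [f"want_lag{l}" for l in (0, 1, 2)]],
            on=["participant_id", "date"],
        )
        for lag in (0, 1, 2):
            np.testing.assert_allclose(
                merged[f"symptom_score_lag{lag}"], merged[f"want_lag{lag}"]
            )


def _make_frame(n_pid=8, n_days=25, seed=1, sigma_b=0.0, rho=0.0, sigma=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pid):
        b = rng.normal(0, sigma_b)
        eps = np.empty(n_days)
        eps[0] = rng.normal(0, sigma)
        for t in range(1, n_days):
            eps[t] = rho * eps[t - 1] + np.sqrt(1 - rho**2) * rng.normal(0, sigma)
        x1 = rng.normal(0, 1, n_days)
        x2 = rng.normal(0, 1, n_days)
        y = 1.0 + 0.5 * x1 - 0.25 * x2 + b + eps
        for d in range(n_days):
            rows.append(
                {"participant_id": f"P{i}", "date": dt.date(2017, 3, 1) + dt.timedelta(days=d),
                 "day_index": d, "y": y[d], "const": 1.0, "x1": x1[d], "x2": x2[d]}
            )
    return ModelFrame(pd.DataFrame(rows), "y", ["const", "x1", "x2"])


class TestRemlAr1:
    def test_fixed_zero_variance_components_collapse_to_ols(self):
        frame = _make_frame()
        fit = fit_lmm_ar1(frame, fix_gamma=0.0, fix_rho=0.0)
        ols = sm.OLS(frame.y, frame.X).fit()
        np.testing.assert_allclose(fit.beta.to_numpy(), ols.params, atol=1e-8)
        np.testing.assert_allclose(fit.se.to_numpy(), ols.bse, atol=1e-8)

    def test_free_fit_on_null_data_close_to_ols(self):
        frame = _make_frame(n_pid=20, n_days=50, seed=2)
        fit = fit_lmm_ar1(frame)
        ols = sm.OLS(frame.y, frame.X).fit()
        np.testing.assert_allclose(fit.beta.to_numpy(), ols.params, atol=5e-2)
        assert abs(fit.rho) < 0.1
        assert fit.sigma_b2 < 0.05

    def test_reml_at_optimum_matches_dense_covariance_oracle(self):
        frame = _make_frame(n_pid=3, n_days=4, seed=3, sigma_b=0.7, rho=0.4)
        fit = fit_lmm_ar1(frame)
        direct = dense_reml_loglik(
            frame.y, frame.X, frame.pids, frame.days,
            fit.sigma_b2, fit.sigma2, fit.rho,
        )
        assert fit.loglik == pytest.approx(direct, abs=1e-6)

    def test_reml_profile_matches_oracle_at_arbitrary_parameters(self):
        frame = _make_frame(n_pid=3, n_days=4, seed=4)
        for sb2, s2, rho in [(0.5, 1.2, 0.3), (0.0, 2.0, 0.0), (1.0, 0.8, -0.4)]:
            got = reml_loglik(frame, sb2, s2, rho)
            want = dense_reml_loglik(frame.y, frame.X, frame.pids, frame.days, sb2, s2, rho)
            assert got == pytest.approx(want, abs=1e-8)

    def test_variance_components_recovered_on_moderate_panel(self):
        frame = _make_frame(n_pid=40, n_days=60, seed=5, sigma_b=1.5, rho=0.45)
        fit = fit_lmm_ar1(frame)
        assert fit.converged
        assert fit.rho == pytest.approx(0.45, abs=0.08)
        assert fit.sigma_b2 == pytest.approx(2.25, rel=0.5)
        assert fit.sigma2 == pytest.approx(1.0, rel=0.15)

    def test_outcome_shift_moves_only_intercept(self):
        frame = _make_frame(seed=6)
        fit0 = fit_lmm_ar1(frame)
        shifted = ModelFrame(
            frame.data.assign(y=frame.data["y"] + 10.0), "y", frame.terms
        )
        fit1 = fit_lmm_ar1(shifted)
        # agreement limited by the optimizer's tolerance on (gamma, rho)
        assert fit1.beta["const"] == pytest.approx(fit0.beta["const"] + 10.0, abs=1e-5)
        np.testing.assert_allclose(
            fit1.beta.drop("const"), fit0.beta.drop("const"), atol=1e-5
        )

    def test_singular_design_names_collinear_column(self):
        frame = _make_frame()
        data = frame.data.assign(x3=2.0 * frame.data["x1"])
        bad = ModelFrame(data, "y", ["const", "x1", "x2", "x3"])
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm_ar1(bad)

    def test_wald_interval_is_plus_minus_1p96_se(self):
        fit = fit_lmm_ar1(_make_frame(seed=7))
        ci = fit.ci95
        np.testing.assert_allclose(ci["ci_low"], fit.beta - 1.96 * fit.se)
        np.testing.assert_allclose(ci["ci_high"], fit.beta + 1.96 * fit.se)


@pytest.fixture(scope="module")
def cohort_panel():
    cfg = SimulationConfig(n_participants=25, days_per_participant=20, seed=31)
    return generate_panel(cfg)


class TestStudyGrid:

    def test_posthoc_triggered_only_for_injected_symptom_effect(self, cohort_panel):
        panel, _ = cohort_panel
        results = run_study_models(panel, include_single_lag=False)
        posthoc = results[results["model_id"].str.contains("posthoc")]
        assert set(posthoc["outcome"]) == {"resting_hr"}
        assert posthoc["model_id"].nunique() == 11
        # the injected effect itself is detected
        lag1 = results[
            (results["model_id"] == "resting_hr~symptom_score|dlag")
            & (results["term"] == "symptom_score_lag1")
        ].iloc[0]
        assert lag1["ci_low"] > 0

    def test_entropy_rows_on_hundredth_scale(self, cohort_panel):
        panel, _ = cohort_panel
        results = run_study_models(
            panel, include_single_lag=False, posthoc=False
        )
        ent = results[results["outcome"] == "sample_entropy"]
        assert (ent["scale"] == 100.0).all()

    def test_results_table_deterministic(self, cohort_panel):
        panel, _ = cohort_panel
        kw = dict(include_single_lag=False, posthoc=False, outcomes=("resting_hr",))
        r1 = run_study_models(panel, **kw)
        r2 = run_study_models(panel, **kw)
        pd.testing.assert_frame_equal(r1, r2)


class TestRequiredSampleSize:
    def test_study_inputs_give_at_most_1422_participant_days(self):
        n = required_sample_size(0.01, alpha=0.05, power=0.90, n_tested=3)
        assert n <= 1422

    def test_returned_n_is_minimal(self):
        from pulsepanel.model import _f2_power

        n = required_sample_size(0.01, alpha=0.05, power=0.90, n_tested=3)
        assert _f2_power(n, 0.01, 0.05, 3) >= 0.90
        assert _f2_power(n - 1, 0.01, 0.05, 3) < 0.90

    def test_larger_effect_needs_fewer_observations(self):
        small = required_sample_size(0.01, n_tested=3)
        big = required_sample_size(0.04, n_tested=3)
        assert big < small

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(0.0)
        with pytest.raises(ValueError):
            required_sample_size(0.01, alpha=1.5)
        with pytest.raises(ValueError):
            required_sample_size(0.01, n_tested=0)

    def test_monte_carlo_power_at_returned_n(self):
        n = required_sample_size(0.01, alpha=0.05, power=0.90, n_tested=3)
        rng = np.random.default_rng(99)
        k = 3
        c = np.full(k, np.sqrt(0.01 / k))  # unit predictors, unit noise: f2 = 0.01
        crit = stats.f.isf(0.05, k, n - k - 1)
        rejections = 0
        n_sim = 1500
        for _ in range(n_sim):
            X = rng.normal(size=(n, k))
            y = X @ c + rng.normal(size=n)
            Xd = np.column_stack([np.ones(n), X])
            beta, rss_full, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            resid = y - Xd @ beta
            rss1 = float(resid @ resid)
            rss0 = float(np.sum((y - y.mean()) ** 2))
            F = ((rss0 - rss1) / k) / (rss1 / (n - k - 1))
            rejections += F > crit
        rate = rejections / n_sim
        mc_se = np.sqrt(0.9 * 0.1 / n_sim)
        assert rate >= 0.90 - 3 * mc_se
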