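"""Tests for the two-tier synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from pulsepanel.biomarkers import resting_heart_rate
from pulsepanel.preprocess import preprocess_day
from pulsepanel.simulate import (
    SimulationConfig,
    generate_panel,
    generate_signal_cohort,
)


def null_config(**kw):
    base = dict(
        beta_symptom_lag1_rhr=0.0, beta_mood_lag0_sampen=0.0,
        diary_missing_prob=0.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


def _residuals(panel, truth, outcome="resting_hr"):
    """Outcome minus its exact generative fixed part and random intercept."""
    coef = truth.coefficients[outcome]
    rows = panel[~panel["lead_in"]].copy()
    lp = np.full(len(rows), coef["const"])
    for col in ("age", "sex_female", "allergy_grass_dust", "mvpa_minutes",
                "no2", "pm10", "med_antihistamine", "med_corticosteroid",
                "med_decongestant", "weekend", "season_birch", "season_alder",
                "season_hazel"):
        lp += coef[col] * rows[col].to_numpy(dtype=float)
    b = rows["participant_id"].map(
        {p: v[outcome] for p, v in truth.random_intercepts.items()}
    ).to_numpy()
    rows["resid"] = rows[outcome].to_numpy() - lp - b
    return rows


def _lag_autocorr(rows, lag):
    pairs = []
    for _, g in rows.groupby("participant_id"):
        r = g.sort_values("date")["resid"].to_numpy()
        pairs.append(np.column_stack([r[:-lag], r[lag:]]))
    a = np.concatenate(pairs)
    return np.corrcoef(a[:, 0], a[:, 1])[0, 1]


class TestDeterminism:
    def test_same_config_and_seed_gives_byte_identical_panels(self):
        cfg = SimulationConfig(n_participants=6, days_per_participant=12, seed=42)
        p1, t1 = generate_panel(cfg)
        p2, t2 = generate_panel(cfg)
        assert p1.to_csv(index=False) == p2.to_csv(index=False)
        assert t1.random_intercepts == t2.random_intercepts

    def test_signal_tier_traces_reproducible(self):
        cfg = SimulationConfig(n_participants=2, days_per_participant=2, seed=7)
        d1 = list(generate_signal_cohort(cfg).iter_days())
        d2 = list(generate_signal_cohort(cfg).iter_days())
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.hr, b.hr)
            np.testing.assert_array_equal(a.t, b.t)

    def test_adding_participants_leaves_existing_ones_unchanged(self):
        small, _ = generate_panel(SimulationConfig(n_participants=4, days_per_participant=8, seed=3))
        big, _ = generate_panel(SimulationConfig(n_participants=7, days_per_participant=8, seed=3))
        pids = sorted(small["participant_id"].unique())
        sub = big[big["participant_id"].isin(pids)].reset_index(drop=True)
        pd.testing.assert_frame_equal(small, sub)


class TestPanelStructure:
    def test_null_model_outcome_is_serially_uncorrelated(self):
        cfg = null_config(
            n_participants=10, days_per_participant=1000, seed=5,
            sigma_b=0.0, rho=0.0,
        )
        panel, truth = generate_panel(cfg)
        rows = _residuals(panel, truth)
        assert abs(_lag_autocorr(rows, 1)) < 0.05

    def test_ar1_residual_autocorrelation_matches_rho(self):
        cfg = null_config(
            n_participants=2, days_per_participant=2500, seed=6,
            sigma_b=0.0, rho=0.5,
        )
        panel, truth = generate_panel(cfg)
        rows = _residuals(panel, truth)
        assert _lag_autocorr(rows, 1) == pytest.approx(0.5, abs=0.05)
        assert _lag_autocorr(rows, 2) == pytest.approx(0.25, abs=0.05)

    def test_symptom_and_mood_marginals_match_study_skew(self):
        cfg = SimulationConfig(n_participants=40, days_per_participant=40, seed=8)
        panel, _ = generate_panel(cfg)
        s = panel["symptom_score"].dropna()
        assert s.min() >= 0 and s.max() <= 44
        assert np.median(s) <= 2  # strongly zero-inflated, median around 1
        assert 0.2 < (s == 0).mean() < 0.5
        m = panel["mood"].dropna()
        assert np.median(m) == 3
        assert set(m.unique()) <= {0, 1, 2, 3, 4}
        items = panel[[c for c in panel.columns if c in
                       ("sneezing", "wheezing", "eye_irritation")]].dropna()
        assert items.to_numpy().max() <= 4
        row_ok = panel.dropna(subset=["symptom_score", "sneezing"])
        from pulsepanel.diary import SYMPTOM_ITEMS
        np.testing.assert_array_equal(
            row_ok[SYMPTOM_ITEMS].sum(axis=1).to_numpy(),
            row_ok["symptom_score"].to_numpy(),
        )

    def test_config_validation_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SimulationConfig(rho=1.0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(sigma_b=-1.0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(diary_missing_prob=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(sigma_e=float("nan")).validate()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(
            n_participants=5, seed=9,
            other_betas={("resting_hr", "mood", 2): -0.1},
        )
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back == cfg


class TestSignalTier:
    def test_flat_noiseless_signal_extracts_exact_resting_hr(self):
        cfg = null_config(
            n_participants=2, days_per_participant=3, seed=10,
            hr_baseline_mean=60.0, hr_baseline_sd=0.0, circadian_amplitude=0.0,
            hr_noise_sd=0.0, activity_bout_rate=0.0, gap_rate=0.0,
            short_day_prob=0.0, sigma_b=0.0, sigma_e=0.0, noncompliant_frac=0.0,
        )
        cohort = generate_signal_cohort(cfg)
        for day in cohort.iter_days():
            pre, _ = preprocess_day(day)
            assert resting_heart_rate(pre) == pytest.approx(60.0, abs=1e-9)

    def test_baseline_marginals_within_monte_carlo_error(self):
        cfg = SimulationConfig(n_participants=100, days_per_participant=1, seed=11)
        cohort = generate_signal_cohort(cfg)
        baselines = np.array(list(cohort.truth.extra["baselines"].values()))
        se_mean = cfg.hr_baseline_sd / np.sqrt(len(baselines))
        assert abs(baselines.mean() - cfg.hr_baseline_mean) < 3 * se_mean
        se_sd = cfg.hr_baseline_sd / np.sqrt(2 * len(baselines))
        assert abs(baselines.std(ddof=1) - cfg.hr_baseline_sd) < 4 * se_sd

    def test_short_day_rate_drives_invalid_day_fraction(self):
        cfg = SimulationConfig(
            n_participants=12, days_per_participant=20, seed=12,
            noncompliant_frac=0.0, diary_missing_prob=0.0,
        )
        cohort = generate_signal_cohort(cfg)
        invalid = []
        for day in cohort.iter_days():
            pre, _ = preprocess_day(day)
            invalid.append(int(np.sum(np.isfinite(pre.hr))) < 2160)
        invalid = np.array(invalid)
        short = cohort.day_plan["short_day"].to_numpy()
        # every planned short day must come out invalid downstream
        assert invalid[short].all()
        n = len(invalid)
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(invalid.mean() - cfg.short_day_prob) < 3 * se + 0.02

    def test_written_cohort_round_trips_through_readers(self, tmp_path):
        from pulsepanel.diary import read_diary_csv
        from pulsepanel.series import read_hr_csv

        cfg = null_config(n_participants=2, days_per_participant=2, seed=13,
                          day_length_range_h=(1.0, 2.0), short_day_prob=0.0)
        cohort = generate_signal_cohort(cfg)
        cohort.write(tmp_path)
        diary = read_diary_csv(tmp_path / "diary.csv")
        assert len(diary) == len(cohort.diary)
        days = read_hr_csv(sorted((tmp_path / "hr").glob("*.csv"))[0])
        orig = [d for d in cohort.iter_days() if d.participant_id == days[0].participant_id]
        got = days[0]
        want = orig[0]
        ok = np.isfinite(want.hr)
        lo = int(np.flatnonzero(ok)[0])  # CSV grid starts at first observation
        np.testing.assert_allclose(
            got.hr[np.isfinite(got.hr)], want.hr[ok], atol=1e-9
        )
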