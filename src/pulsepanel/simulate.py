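"""Synthetic telemonitoring cohorts with known, injectable effect sizes.

No raw data from the original telemonitoring study are deposited, so this
module generates cohorts with the statistical structure the analysis
assumes, at two tiers:

* **Tier A** (:func:`generate_panel`) draws outcome-level panels directly
  from the estimating model's generative process — daily resting heart rate
  and sample entropy equal a linear predictor in lagged allergy burden and
  covariates plus a participant random intercept and AR(1) day-to-day
  residuals — for parameter-recovery and type-I-error testing.
* **Tier B** (:func:`generate_signal_cohort`) emits full signal-level data:
  1 Hz daytime heart-rate traces (baseline + circadian dip + activity bouts
  + sensor noise, with missing gaps), daily diaries, a participant table and
  a calendar table.  The trace's quiet floor is shifted day by day by the
  ground-truth lagged symptom effect, so the resting heart rate *extracted
  by the preprocessing pipeline* carries the injected association.  No
  forward model from mood to heart-rate entropy is assumed, so the
  mood→entropy effect is injected at tier A only.

Every draw descends from one root seed through per-participant (and
per-day) substreams, so regenerating with the same config reproduces the
data bit for bit and adding participants does not perturb existing ones.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .diary import MED_CLASSES, SYMPTOM_ITEMS
from .series import HeartRateSeries

SECONDS_PER_DAY = 86400

#: covariate effects used when generating outcomes (recorded in GroundTruth)
TRUE_COVARIATE_EFFECTS = {
    "resting_hr": {
        "const": 55.0, "age": 0.05, "sex_female": 5.0, "allergy_grass_dust": 0.5,
        "mvpa_minutes": -0.01, "no2": 0.03, "pm10": 0.02,
        "med_antihistamine": -0.3, "med_corticosteroid": 0.3, "med_decongestant": 1.0,
        "weekend": -0.5, "season_birch": 0.3, "season_alder": 0.2, "season_hazel": 0.2,
    },
    "sample_entropy": {
        "const": 0.40, "age": -0.001, "sex_female": 0.04, "allergy_grass_dust": 0.0,
        "mvpa_minutes": 0.0001, "no2": 0.0, "pm10": 0.0,
        "med_antihistamine": 0.0, "med_corticosteroid": 0.0, "med_decongestant": 0.0,
        "weekend": 0.005, "season_birch": 0.0, "season_alder": 0.0, "season_hazel": 0.0,
    },
}

_SYMPTOM_ITEM_WEIGHTS = np.array(
    [0.03, 0.04, 0.07, 0.16, 0.20, 0.10, 0.12, 0.07, 0.07, 0.05, 0.09]
)  # sneezing / runny nose / fatigue dominate, wheezing rare


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-condition defaults.

    The defaults mirror the study: 72 participants averaging 35 analysis
    days, a next-day symptom effect of +0.08 bpm per symptom point on
    resting heart rate and a same-day mood effect of +0.80e-2 entropy units
    per mood point, skewed zero-inflated symptom scores (median ~1, IQR
    ~0-5), mood concentrated at 3, 1 Hz daytime traces of 10-16 h starting
    between 06:00 and 09:00.
    """

    n_participants: int = 72
    days_per_participant: int | tuple[int, int] = 35
    seed: int = 0
    start_date: str = "2017-01-16"
    start_spread_days: int = 60

    # injected exposure effects (per-point) and variance components
    beta_symptom_lag1_rhr: float = 0.08    # bpm per symptom point, next day
    beta_mood_lag0_sampen: float = 0.008   # entropy units per mood point, same day
    other_betas: dict = dataclasses.field(default_factory=dict)
    sigma_b: float = 6.0        # between-participant SD of resting HR, bpm
    sigma_e: float = 2.5        # residual day-to-day SD of resting HR, bpm
    rho: float = 0.3            # AR(1) residual correlation per day
    sigma_b_entropy: float = 0.09
    sigma_e_entropy: float = 0.05
    rho_entropy: float = 0.3

    # signal-level trace model
    hr_baseline_mean: float = 62.0   # bpm
    hr_baseline_sd: float = 6.0      # bpm between participants
    circadian_amplitude: float = 3.0  # bpm, afternoon dip
    hr_noise_sd: float = 2.0         # bpm white sensor noise at 1 Hz
    activity_bout_rate: float = 4.0  # bouts per 12 h of wear
    bout_amplitude_range: tuple[float, float] = (20.0, 60.0)
    gap_rate: float = 2.0            # gaps per hour
    gap_short_range_s: tuple[int, int] = (2, 15)
    gap_long_range_s: tuple[int, int] = (30, 600)
    gap_long_frac: float = 0.2
    day_start_range_h: tuple[float, float] = (6.0, 9.0)
    day_length_range_h: tuple[float, float] = (10.0, 16.0)
    short_day_prob: float = 0.10     # days with < 6 h of data
    short_day_length_range_h: tuple[float, float] = (2.5, 5.5)
    noncompliant_frac: float = 0.10  # participants with < 10 valid days
    noncompliant_days_range: tuple[int, int] = (4, 9)

    # diary processes
    diary_missing_prob: float = 0.05
    symptom_mu: float = 0.59         # latent log-intensity location
    symptom_sigma: float = 1.65      # latent log-intensity scale
    symptom_rho: float = 0.6         # day-to-day latent correlation
    mood_probs: tuple[float, ...] = (0.03, 0.07, 0.15, 0.60, 0.15)
    mood_rho: float = 0.5

    # daily covariate processes
    mvpa_gamma_shape: float = 2.0
    mvpa_gamma_scale: float = 15.0   # minutes

    def validate(self) -> None:
        def _fin(*vals):
            if not np.all(np.isfinite(np.asarray(vals, dtype=float))):
                raise ValueError("non-finite value in simulation config")

        _fin(self.sigma_b, self.sigma_e, self.rho, self.sigma_b_entropy,
             self.sigma_e_entropy, self.rho_entropy, self.hr_baseline_mean,
             self.hr_baseline_sd, self.circadian_amplitude, self.hr_noise_sd,
             self.activity_bout_rate, self.gap_rate,
             self.beta_symptom_lag1_rhr, self.beta_mood_lag0_sampen,
             *self.other_betas.values())
        for name in ("sigma_b", "sigma_e", "sigma_b_entropy", "sigma_e_entropy",
                     "hr_baseline_sd", "hr_noise_sd", "circadian_amplitude",
                     "activity_bout_rate", "gap_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho", "rho_entropy", "symptom_rho", "mood_rho"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("diary_missing_prob", "short_day_prob", "noncompliant_frac",
                     "gap_long_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if abs(sum(self.mood_probs) - 1.0) > 1e-9 or len(self.mood_probs) != 5:
            raise ValueError("mood_probs must be 5 probabilities summing to 1")

    # -- flat key-value (de)serialization -----------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["other_betas"] = {
            f"{o}:{e}:{l}": v for (o, e, l), v in self.other_betas.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        raw = d.pop("other_betas", {}) or {}
        betas = {}
        for key, v in raw.items():
            o, e, l = key.split(":")
            betas[(o, e, int(l))] = float(v)
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in fields}
        for k in list(kwargs):
            if isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        return cls(other_betas=betas, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def exposure_betas(self) -> dict[tuple[str, str, int], float]:
        """Full (outcome, exposure, lag) -> beta map, zeros filled in."""
        betas = {
            (o, e, l): 0.0
            for o in ("resting_hr", "sample_entropy")
            for e in ("symptom_score", "mood")
            for l in (0, 1, 2)
        }
        betas[("resting_hr", "symptom_score", 1)] = self.beta_symptom_lag1_rhr
        betas[("sample_entropy", "mood", 0)] = self.beta_mood_lag0_sampen
        betas.update(self.other_betas)
        return betas


@dataclasses.dataclass
class GroundTruth:
    """Exact parameters behind a generated dataset (JSON-serializable)."""

    coefficients: dict
    sigma_b2: dict
    sigma2: dict
    rho: dict
    random_intercepts: dict
    extra: dict = dataclasses.field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# elementary processes
# ---------------------------------------------------------------------------

def _participant_rng(seed: int, i: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, i, *stream]))


def _ar1_unit(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary AR(1) with unit marginal variance over consecutive days."""
    e = rng.standard_normal(n)
    z = np.empty(n)
    z[0] = e[0]
    c = np.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + c * e[t]
    return z


def _symptom_scores(rng, n, cfg: SimulationConfig) -> np.ndarray:
    """Zero-inflated, serially correlated daily symptom scores on 0..44.

    A latent AR(1) log-intensity is floored to an integer: scores are zero
    whenever the intensity stays below 1 (about a third of days) and heavy
    right tails reproduce the skew of real symptom diaries.
    """
    z = _ar1_unit(rng, n, cfg.symptom_rho)
    s = np.floor(np.exp(cfg.symptom_mu + cfg.symptom_sigma * z))
    return np.clip(s, 0, 44).astype(int)


def _mood_scores(rng, n, cfg: SimulationConfig) -> np.ndarray:
    """Ordinal 0..4 mood from a latent AR(1) cut at fixed quantiles."""
    z = _ar1_unit(rng, n, cfg.mood_rho)
    cuts = stats.norm.ppf(np.cumsum(cfg.mood_probs)[:-1])
    return np.searchsorted(cuts, z).astype(int)


def _allocate_items(rng, scores: np.ndarray) -> np.ndarray:
    """Split daily total scores over the 11 items, each capped at 4."""
    out = np.zeros((len(scores), len(SYMPTOM_ITEMS)), dtype=int)
    for d, total in enumerate(scores):
        remaining = int(total)
        counts = np.zeros(len(SYMPTOM_ITEMS), dtype=int)
        w = _SYMPTOM_ITEM_WEIGHTS.copy()
        while remaining > 0:
            open_items = counts < 4
            p = w * open_items
            p = p / p.sum()
            draw = rng.multinomial(remaining, p)
            draw = np.minimum(draw, 4 - counts)
            counts += draw
            remaining = int(total - counts.sum())
        out[d] = counts
    return out


def season_flags(date: dt.date) -> tuple[int, int, int]:
    """(birch, alder, hazel) pollen-season membership for a calendar date.

    Fixed Belgian-style windows: hazel Jan 20 - Mar 10, alder Feb 1 - Mar 20,
    birch Mar 25 - Apr 30 (every year).
    """
    y = date.year
    hazel = dt.date(y, 1, 20) <= date <= dt.date(y, 3, 10)
    alder = dt.date(y, 2, 1) <= date <= dt.date(y, 3, 20)
    birch = dt.date(y, 3, 25) <= date <= dt.date(y, 4, 30)
    return int(birch), int(alder), int(hazel)


def make_calendar(dates) -> pd.DataFrame:
    """Calendar covariate table: month, weekend and pollen-season flags."""
    dates = sorted(set(dates))
    rows = []
    for d in dates:
        birch, alder, hazel = season_flags(d)
        rows.append(
            {
                "date": d,
                "month": d.month,
                "weekend": int(d.weekday() >= 5),
                "season_birch": birch,
                "season_alder": alder,
                "season_hazel": hazel,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# participant-level building block shared by both tiers
# ---------------------------------------------------------------------------

N_LEAD_IN = 2  # extra diary days before the first outcome day (for lags)


def _participant_block(cfg: SimulationConfig, i: int, tier_b: bool) -> dict:
    rng = _participant_rng(cfg.seed, i)
    pid = f"P{i:03d}"

    noncompliant = tier_b and (rng.uniform() < cfg.noncompliant_frac)
    if noncompliant:
        lo, hi = cfg.noncompliant_days_range
        n_days = int(rng.integers(lo, hi + 1))
    elif isinstance(cfg.days_per_participant, (tuple, list)):
        lo, hi = cfg.days_per_participant
        n_days = int(rng.integers(lo, hi + 1))
    else:
        n_days = int(cfg.days_per_participant)

    start = dt.date.fromisoformat(cfg.start_date) + dt.timedelta(
        days=int(rng.integers(0, cfg.start_spread_days + 1))
    )
    n_total = n_days + N_LEAD_IN
    dates = [start + dt.timedelta(days=d - N_LEAD_IN) for d in range(n_total)]

    age = float(np.clip(np.round(rng.normal(40.0, 11.0)), 20, 75))
    sex_female = int(rng.uniform() < 0.65)
    allergy = int(rng.uniform() < 0.74)
    no2 = float(np.clip(rng.normal(18.0, 4.0), 2.0, None))
    pm10 = float(np.clip(rng.normal(22.0, 5.0), 2.0, None))

    antihist_user = rng.uniform() < 0.90
    cortico_user = rng.uniform() < 0.32
    meds = np.column_stack(
        [
            (rng.uniform(size=n_total) < (0.7 if antihist_user else 0.0)).astype(int),
            (rng.uniform(size=n_total) < (0.8 if cortico_user else 0.0)).astype(int),
            (rng.uniform(size=n_total) < 0.01).astype(int),
        ]
    )
    mvpa = rng.gamma(cfg.mvpa_gamma_shape, cfg.mvpa_gamma_scale, size=n_total)

    symptoms = _symptom_scores(rng, n_total, cfg)
    mood = _mood_scores(rng, n_total, cfg)
    items = _allocate_items(rng, symptoms)
    diary_missing = rng.uniform(size=n_total) < cfg.diary_missing_prob

    b_rhr = rng.normal(0.0, cfg.sigma_b)
    b_ent = rng.normal(0.0, cfg.sigma_b_entropy)
    eps_rhr = cfg.sigma_e * _ar1_unit(rng, n_days, cfg.rho) if cfg.sigma_e > 0 else np.zeros(n_days)
    eps_ent = (
        cfg.sigma_e_entropy * _ar1_unit(rng, n_days, cfg.rho_entropy)
        if cfg.sigma_e_entropy > 0
        else np.zeros(n_days)
    )

    return {
        "pid": pid, "i": i, "dates": dates, "n_days": n_days,
        "noncompliant": noncompliant, "age": age, "sex_female": sex_female,
        "allergy": allergy, "no2": no2, "pm10": pm10, "meds": meds,
        "mvpa": mvpa, "symptoms": symptoms, "mood": mood, "items": items,
        "diary_missing": diary_missing, "b_rhr": b_rhr, "b_ent": b_ent,
        "eps_rhr": eps_rhr, "eps_ent": eps_ent, "rng": rng,
    }


def _linear_predictor(cfg: SimulationConfig, blk: dict, outcome: str) -> np.ndarray:
    """Fixed-effect part of the outcome over the non-lead-in days."""
    eff = TRUE_COVARIATE_EFFECTS[outcome]
    betas = cfg.exposure_betas()
    n_days = blk["n_days"]
    lp = np.full(n_days, eff["const"])
    lp += eff["age"] * blk["age"] + eff["sex_female"] * blk["sex_female"]
    lp += eff["allergy_grass_dust"] * blk["allergy"]
    lp += eff["no2"] * blk["no2"] + eff["pm10"] * blk["pm10"]
    for d in range(n_days):
        g = d + N_LEAD_IN  # index into full (lead-in included) daily arrays
        date = blk["dates"][g]
        birch, alder, hazel = season_flags(date)
        lp[d] += eff["mvpa_minutes"] * blk["mvpa"][g]
        lp[d] += eff["med_antihistamine"] * blk["meds"][g, 0]
        lp[d] += eff["med_corticosteroid"] * blk["meds"][g, 1]
        lp[d] += eff["med_decongestant"] * blk["meds"][g, 2]
        lp[d] += eff["weekend"] * (date.weekday() >= 5)
        lp[d] += eff["season_birch"] * birch + eff["season_alder"] * alder
        lp[d] += eff["season_hazel"] * hazel
        for exposure, series in (("symptom_score", blk["symptoms"]), ("mood", blk["mood"])):
            for lag in (0, 1, 2):
                lp[d] += betas[(outcome, exposure, lag)] * series[g - lag]
    return lp


def _truth(cfg: SimulationConfig, blocks: list[dict]) -> GroundTruth:
    betas = cfg.exposure_betas()
    coefficients = {}
    for outcome in ("resting_hr", "sample_entropy"):
        coef = dict(TRUE_COVARIATE_EFFECTS[outcome])
        for (o, e, l), v in betas.items():
            if o == outcome:
                coef[f"{e}_lag{l}"] = v
        coefficients[outcome] = coef
    return GroundTruth(
        coefficients=coefficients,
        sigma_b2={"resting_hr": cfg.sigma_b ** 2, "sample_entropy": cfg.sigma_b_entropy ** 2},
        sigma2={"resting_hr": cfg.sigma_e ** 2, "sample_entropy": cfg.sigma_e_entropy ** 2},
        rho={"resting_hr": cfg.rho, "sample_entropy": cfg.rho_entropy},
        random_intercepts={
            b["pid"]: {"resting_hr": b["b_rhr"], "sample_entropy": b["b_ent"]}
            for b in blocks
        },
    )


def _diary_frame(blocks: list[dict]) -> pd.DataFrame:
    rows = []
    for blk in blocks:
        for g, date in enumerate(blk["dates"]):
            if blk["diary_missing"][g]:
                item_vals = [np.nan] * len(SYMPTOM_ITEMS)
                mood_val, med_vals = np.nan, [np.nan] * 3
            else:
                item_vals = blk["items"][g].tolist()
                mood_val = int(blk["mood"][g])
                med_vals = blk["meds"][g].tolist()
            row = {"participant_id": blk["pid"], "date": date}
            row.update(dict(zip(SYMPTOM_ITEMS, item_vals)))
            row["mood"] = mood_val
            row.update(dict(zip(MED_CLASSES, med_vals)))
            rows.append(row)
    return pd.DataFrame(rows)


def _participants_frame(blocks: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": b["pid"], "age": b["age"],
                "sex_female": b["sex_female"], "allergy_grass_dust": b["allergy"],
                "no2": b["no2"], "pm10": b["pm10"],
            }
            for b in blocks
        ]
    )


# ---------------------------------------------------------------------------
# tier A: outcome-level panels
# ---------------------------------------------------------------------------

def generate_panel(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a daily panel straight from the mixed-model generative process.

    Returns a tidy frame with one row per participant-day: both outcomes,
    the (possibly missing) reported exposures and medication flags, all
    adjustment covariates, and a ``lead_in`` flag on the two pre-study diary
    days (outcomes missing there; their exposures feed the lags of the first
    analysis days).  The exact parameters come back as a
    :class:`GroundTruth`.
    """
    config.validate()
    blocks = [_participant_block(config, i, tier_b=False) for i in range(config.n_participants)]
    rows = []
    for blk in blocks:
        lp_rhr = _linear_predictor(config, blk, "resting_hr")
        lp_ent = _linear_predictor(config, blk, "sample_entropy")
        y_rhr = lp_rhr + blk["b_rhr"] + blk["eps_rhr"]
        y_ent = lp_ent + blk["b_ent"] + blk["eps_ent"]
        for g, date in enumerate(blk["dates"]):
            lead_in = g < N_LEAD_IN
            d = g - N_LEAD_IN
            birch, alder, hazel = season_flags(date)
            missing = blk["diary_missing"][g]
            row = {
                "participant_id": blk["pid"], "date": date, "lead_in": lead_in,
                "resting_hr": np.nan if lead_in else y_rhr[d],
                "sample_entropy": np.nan if lead_in else y_ent[d],
                "symptom_score": np.nan if missing else float(blk["symptoms"][g]),
                "mood": np.nan if missing else float(blk["mood"][g]),
                "age": blk["age"], "sex_female": blk["sex_female"],
                "allergy_grass_dust": blk["allergy"], "no2": blk["no2"],
                "pm10": blk["pm10"], "mvpa_minutes": blk["mvpa"][g],
                "weekend": int(date.weekday() >= 5),
                "season_birch": birch, "season_alder": alder, "season_hazel": hazel,
            }
            for j, item in enumerate(SYMPTOM_ITEMS):
                row[item] = np.nan if missing else int(blk["items"][g, j])
            for j, med in enumerate(MED_CLASSES):
                row[med] = np.nan if missing else int(blk["meds"][g, j])
            rows.append(row)
    panel = pd.DataFrame(rows)
    return panel, _truth(config, blocks)


# ---------------------------------------------------------------------------
# tier B: signal-level cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SignalCohort:
    """A full signal-level synthetic cohort.

    Heart-rate traces are produced lazily by :meth:`iter_days` (each day is
    deterministically regenerable from the seed), diaries and the
    participant/calendar tables eagerly.  ``day_plan`` records per-day
    ground truth: the injected resting-level shift and the short-day flag.
    """

    config: SimulationConfig
    diary: pd.DataFrame
    participants: pd.DataFrame
    calendar: pd.DataFrame
    truth: GroundTruth
    day_plan: pd.DataFrame
    _blocks: list[dict] = dataclasses.field(default_factory=list, repr=False)

    def iter_days(self) -> Iterator[HeartRateSeries]:
        for blk in self._blocks:
            for d in range(blk["n_days"]):
                yield _build_day_trace(self.config, blk, d)

    def write(self, outdir) -> None:
        """Write the cohort in the CSV dialects the pipeline reads."""
        from .series import write_hr_csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "hr").mkdir(exist_ok=True)
        for blk in self._blocks:
            days = [_build_day_trace(self.config, blk, d) for d in range(blk["n_days"])]
            write_hr_csv(days, outdir / "hr" / f"{blk['pid']}.csv")
        self.diary.to_csv(outdir / "diary.csv", index=False)
        self.participants.to_csv(outdir / "participants.csv", index=False)
        self.calendar.to_csv(outdir / "calendar.csv", index=False)
        self.truth.to_json(outdir / "ground_truth.json")
        self.config.to_yaml(outdir / "config.yaml")


def _build_day_trace(cfg: SimulationConfig, blk: dict, d: int) -> HeartRateSeries:
    """One 1 Hz daytime trace; fully determined by (seed, participant, day)."""
    rng = _participant_rng(cfg.seed, blk["i"], d + N_LEAD_IN, 77)
    date = blk["dates"][d + N_LEAD_IN]

    short = rng.uniform() < cfg.short_day_prob
    lo, hi = cfg.day_start_range_h
    start_s = int(rng.uniform(lo, hi) * 3600)
    if short:
        llo, lhi = cfg.short_day_length_range_h
    else:
        llo, lhi = cfg.day_length_range_h
    dur_s = int(rng.uniform(llo, lhi) * 3600)
    dur_s = min(dur_s, SECONDS_PER_DAY - 1 - start_s)
    t = np.arange(start_s, start_s + dur_s, dtype=float)

    delta = blk["delta"][d]
    level = blk["baseline"] + delta
    trough = 14.0 * 3600
    hr = level - cfg.circadian_amplitude * np.cos(2 * np.pi * (t - trough) / SECONDS_PER_DAY)
    if cfg.hr_noise_sd > 0:
        hr += rng.normal(0.0, cfg.hr_noise_sd, size=len(t))

    n_bouts = rng.poisson(cfg.activity_bout_rate * dur_s / 43200.0)
    for _ in range(n_bouts):
        center = rng.uniform(start_s, start_s + dur_s)
        half = 0.5 * rng.lognormal(np.log(900.0), 0.5)
        amp = rng.uniform(*cfg.bout_amplitude_range)
        s, e = center - half, center + half
        ramp = np.clip((t - s) / 120.0, 0.0, 1.0) * np.clip((e - t) / 120.0, 0.0, 1.0)
        hr += amp * ramp
    np.clip(hr, 25.0, 250.0, out=hr)

    n_gaps = rng.poisson(cfg.gap_rate * dur_s / 3600.0)
    for _ in range(n_gaps):
        g0 = int(rng.uniform(0, dur_s))
        if rng.uniform() < cfg.gap_long_frac:
            glen = int(rng.integers(*cfg.gap_long_range_s))
        else:
            glen = int(rng.integers(*cfg.gap_short_range_s))
        hr[g0 : g0 + glen] = np.nan
    if not np.any(np.isfinite(hr)):  # pathological all-gap day
        hr[0] = level
    return HeartRateSeries(blk["pid"], date, t, hr, rate_hz=1.0)


def generate_signal_cohort(config: SimulationConfig) -> SignalCohort:
    """Generate a full signal-level cohort (1 Hz traces + diaries + tables).

    The daily quiet-floor level of each trace is ``baseline_i + delta_id``
    where ``delta_id`` sums the ground-truth lagged exposure effects on
    resting heart rate, the participant's random intercept, and an AR(1)
    residual — so the resting heart rate the pipeline extracts carries the
    injected associations.  The mood→entropy effect is *not* injected at
    the signal level (no accepted forward model); test it at tier A.
    """
    config.validate()
    blocks = [
        _participant_block(config, i, tier_b=True) for i in range(config.n_participants)
    ]
    betas = config.exposure_betas()
    plan_rows = []
    for blk in blocks:
        rng = blk["rng"]
        blk["baseline"] = float(
            np.clip(rng.normal(config.hr_baseline_mean, config.hr_baseline_sd), 35.0, 120.0)
        )
        delta = np.zeros(blk["n_days"])
        for d in range(blk["n_days"]):
            g = d + N_LEAD_IN
            for exposure, series in (("symptom_score", blk["symptoms"]), ("mood", blk["mood"])):
                for lag in (0, 1, 2):
                    delta[d] += betas[("resting_hr", exposure, lag)] * series[g - lag]
        delta += blk["b_rhr"] + blk["eps_rhr"]
        blk["delta"] = delta
        for d in range(blk["n_days"]):
            day_rng = _participant_rng(config.seed, blk["i"], d + N_LEAD_IN, 77)
            short = day_rng.uniform() < config.short_day_prob
            plan_rows.append(
                {
                    "participant_id": blk["pid"],
                    "date": blk["dates"][d + N_LEAD_IN],
                    "delta": delta[d],
                    "short_day": short,
                    "noncompliant": blk["noncompliant"],
                }
            )

    truth = _truth(config, blocks)
    truth.extra = {
        "baselines": {b["pid"]: b["baseline"] for b in blocks},
        "entropy_effect_injected": False,
    }
    all_dates = [d for b in blocks for d in b["dates"]]
    return SignalCohort(
        config=config,
        diary=_diary_frame(blocks),
        participants=_participants_frame(blocks),
        calendar=make_calendar(all_dates),
        truth=truth,
        day_plan=pd.DataFrame(plan_rows),
        _blocks=blocks,
    )
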