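"""End-to-end pipeline orchestration: simulate → preprocess → features →
score → fit → report, with a manifest for reproducibility.

Every stage is a thin call into the library modules; re-running with the
same config and inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import (
    ENTROPY_WINDOW_SAMPLES,
    EntropyParams,
    compute_daily_biomarkers,
)
from .diary import MIN_VALID_DAYS, read_diary_csv, score_diary
from .model import ADJUSTMENT_COVARIATES, run_study_models
from .preprocess import (
    DEFAULT_BANDWIDTH_S,
    DEFAULT_BIN_S,
    DEFAULT_MAX_GAP_S,
    preprocess_day,
)
from .series import read_hr_csv, write_hr_csv
from .simulate import SimulationConfig, generate_signal_cohort


@dataclasses.dataclass
class RunConfig:
    """Pipeline settings; defaults are the study's stated constants."""

    outdir: str = "run"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None  # used when simulate is False
    # preprocessing
    max_gap_s: float = DEFAULT_MAX_GAP_S
    bandwidth_s: float = DEFAULT_BANDWIDTH_S
    bin_s: float = DEFAULT_BIN_S
    # entropy
    entropy_m: int = 2
    entropy_r_coefficient: float = 0.15
    entropy_window_samples: int = ENTROPY_WINDOW_SAMPLES
    # mvpa
    mvpa_fraction: float = 0.40
    max_hr_rule: str = "220_minus_age"
    # filters
    min_samples: int = ENTROPY_WINDOW_SAMPLES
    min_valid_days: int = MIN_VALID_DAYS
    iqr_multiplier: float = 1.5
    # models
    lags: tuple[int, ...] = (0, 1, 2)
    include_single_lag: bool = True
    posthoc: bool = True
    # simulation overrides (flat keys of SimulationConfig)
    simulation: dict = dataclasses.field(default_factory=dict)
    write_intermediate: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lags"] = list(self.lags)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "lags" in d:
            d["lags"] = tuple(d["lags"])
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _simulation_config(cfg: RunConfig) -> SimulationConfig:
    base = SimulationConfig(seed=cfg.seed).to_dict()
    base.update(cfg.simulation or {})
    base["seed"] = cfg.seed
    return SimulationConfig.from_dict(base)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages and write the artifact directory.

    Returns a summary dict: the flow report, the results table path, and
    convergence status.  Raises ValueError on invalid configuration or
    empty cohorts; model non-convergence is reported, not raised.
    """
    if not cfg.simulate and not cfg.input_dir:
        raise ValueError("input_dir required when simulate is false")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs ------------------------------------------------------------
    if cfg.simulate:
        cohort = generate_signal_cohort(_simulation_config(cfg))
        day_iter = cohort.iter_days()
        diary = cohort.diary
        participants = cohort.participants
        calendar = cohort.calendar
        if cfg.write_intermediate:
            cohort.truth.to_json(out / "ground_truth.json")
    else:
        if not cfg.input_dir:
            raise ValueError("input_dir required when simulate is false")
        indir = Path(cfg.input_dir)
        day_iter = (
            s for f in sorted((indir / "hr").glob("*.csv")) for s in read_hr_csv(f)
        )
        diary = read_diary_csv(indir / "diary.csv")
        participants = pd.read_csv(indir / "participants.csv", dtype={"participant_id": str})
        calendar = pd.read_csv(indir / "calendar.csv")
        calendar["date"] = pd.to_datetime(calendar["date"]).dt.date

    # --- preprocess --------------------------------------------------------
    preprocessed = []
    stage_log = {"n_days_preprocessed": 0, "n_gaps_filled": 0, "n_gaps_left": 0}
    for raw in day_iter:
        day01, log = preprocess_day(
            raw, max_gap_s=cfg.max_gap_s, bandwidth_s=cfg.bandwidth_s, bin_s=cfg.bin_s
        )
        preprocessed.append(day01)
        stage_log["n_days_preprocessed"] += 1
        stage_log["n_gaps_filled"] += log.n_gaps_filled
        stage_log["n_gaps_left"] += log.n_gaps_left
    if cfg.write_intermediate:
        write_hr_csv(preprocessed, out / "preprocessed_0p1hz.csv")

    # --- daily features ----------------------------------------------------
    ages = dict(zip(participants["participant_id"], participants["age"]))
    biomarkers = compute_daily_biomarkers(
        preprocessed,
        participant_age=ages,
        entropy_params=EntropyParams(
            m=cfg.entropy_m,
            r_coefficient=cfg.entropy_r_coefficient,
            window_samples=cfg.entropy_window_samples,
        ),
        mvpa_fraction=cfg.mvpa_fraction,
        max_hr_rule=cfg.max_hr_rule,
        min_samples=cfg.min_samples,
        iqr_multiplier=cfg.iqr_multiplier,
    )
    biomarkers.to_csv(out / "biomarkers.csv", index=False)

    # --- score + filters + fit ---------------------------------------------
    from .diary import compliance_filter, mark_valid_days

    scored = score_diary(diary)
    merged = mark_valid_days(biomarkers, scored, min_samples=cfg.min_samples)
    kept, report = compliance_filter(merged, cfg.min_valid_days)
    for outcome, flag in [("resting_hr", "outlier_rhr"), ("sample_entropy", "outlier_sampen")]:
        bad = kept[flag].eq(True)
        kept.loc[bad, outcome] = np.nan

    panel = kept.merge(participants, on="participant_id", how="left")
    cal = calendar.copy()
    panel["_d"] = pd.to_datetime(panel["date"])
    cal["_d"] = pd.to_datetime(cal["date"])
    panel = panel.merge(cal.drop(columns=["date"]), on="_d", how="left").drop(columns=["_d"])

    results = run_study_models(
        panel,
        exposure_source=scored,
        lags=cfg.lags,
        include_single_lag=cfg.include_single_lag,
        posthoc=cfg.posthoc,
        adjust=ADJUSTMENT_COVARIATES,
    )
    results.to_csv(out / "results.csv", index=False)

    flow = report.to_dict()
    with open(out / "flow_report.json", "w") as fh:
        json.dump(flow, fh, indent=1, sort_keys=True)

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_counts": stage_log,
        "flow": flow,
        "n_models": int(results["model_id"].nunique()),
        "all_converged": bool(results["converged"].all()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
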