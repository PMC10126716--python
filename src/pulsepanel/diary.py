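"""Daily diary scoring and cohort validity/compliance filters.

Each evening participants rate 11 allergic-rhinitis symptoms on discrete
0 (never) – 4 (always) sliders, their overall mood on a 0 (worst) – 4 (best)
scale, and tick the medication classes taken that day.  The daily allergy
symptom score is the plain sum of the 11 items (range 0–44).

A *valid day* couples the diary with the wearable: at least 6 h of
heart-rate data (2160 samples at 0.1 Hz) plus complete symptom, mood and
medication reports.  Participants contributing fewer than 10 valid days are
considered non-compliant and are excluded.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .biomarkers import ENTROPY_WINDOW_SAMPLES

SYMPTOM_ITEMS = [
    "wheezing",
    "dyspnoea",
    "coughing",
    "sneezing",
    "runny_stuffy_nose",
    "itching",
    "fatigue",
    "headache",
    "bad_sleep",
    "difficulty_concentrating",
    "eye_irritation",
]
MED_CLASSES = ["med_antihistamine", "med_corticosteroid", "med_decongestant"]
SYMPTOM_SCORE_MAX = 4 * len(SYMPTOM_ITEMS)  # 44
MIN_VALID_DAYS = 10

DIARY_COLUMNS = ["participant_id", "date"] + SYMPTOM_ITEMS + ["mood"] + MED_CLASSES


@dataclasses.dataclass
class CohortFilterReport:
    """Flow-diagram counts for the validity and compliance filters."""

    n_participants_in: int
    n_participants_out: int
    n_days_in: int
    n_days_out: int
    exclusions: dict = dataclasses.field(default_factory=dict)

    @property
    def n_participants_excluded(self) -> int:
        return self.n_participants_in - self.n_participants_out

    @property
    def n_days_excluded(self) -> int:
        return self.n_days_in - self.n_days_out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_item_range(values: pd.Series, name: str) -> None:
    v = values.dropna()
    if len(v) and (v.min() < 0 or v.max() > 4 or np.any(v != np.round(v))):
        raise ValueError(f"{name} scores must be integers in 0..4")


def symptom_score(entry: Mapping[str, float]) -> float:
    """Sum of the 11 symptom items (0–44); missing if any item is missing."""
    vals = [entry.get(item, np.nan) for item in SYMPTOM_ITEMS]
    arr = np.asarray(vals, dtype=float)
    if np.any(~np.isfinite(arr)):
        return float("nan")
    if arr.min() < 0 or arr.max() > 4:
        raise ValueError("symptom items must lie in 0..4")
    return float(arr.sum())


def score_diary(diary: pd.DataFrame) -> pd.DataFrame:
    """Add ``symptom_score`` and ``diary_complete`` columns to a diary table.

    ``diary_complete`` is True when all 11 items, mood, and all three
    medication flags are reported; "no medication" is an explicit all-zero
    report, distinct from a missing one.
    """
    missing = [c for c in DIARY_COLUMNS if c not in diary.columns]
    if missing:
        raise ValueError(f"diary table missing columns: {missing}")
    out = diary.copy()
    for item in SYMPTOM_ITEMS:
        _check_item_range(out[item], item)
    _check_item_range(out["mood"], "mood")
    items = out[SYMPTOM_ITEMS].to_numpy(dtype=float)
    complete_items = np.all(np.isfinite(items), axis=1)
    score = np.where(complete_items, items.sum(axis=1), np.nan)
    out["symptom_score"] = score
    meds = out[MED_CLASSES].to_numpy(dtype=float)
    out["diary_complete"] = (
        complete_items
        & np.isfinite(out["mood"].to_numpy(dtype=float))
        & np.all(np.isfinite(meds), axis=1)
    )
    return out


def valid_day(n_samples_0p1hz: int, entry: Mapping[str, float],
              min_samples: int = ENTROPY_WINDOW_SAMPLES) -> bool:
    """True iff the day has >= 6 h of heart-rate data and a complete diary."""
    if n_samples_0p1hz < min_samples:
        return False
    if not np.isfinite(symptom_score(entry)):
        return False
    mood = entry.get("mood", np.nan)
    if mood is None or not np.isfinite(float(mood)):
        return False
    for med in MED_CLASSES:
        v = entry.get(med, np.nan)
        if v is None or not np.isfinite(float(v)):
            return False
    return True


def mark_valid_days(
    biomarkers: pd.DataFrame,
    diary: pd.DataFrame,
    min_samples: int = ENTROPY_WINDOW_SAMPLES,
) -> pd.DataFrame:
    """Merge biomarker and scored-diary tables and flag valid participant-days.

    Days present in only one table count as invalid (the missing half of the
    record is, by definition, unavailable).
    """
    scored = score_diary(diary) if "diary_complete" not in diary.columns else diary
    merged = biomarkers.merge(
        scored, on=["participant_id", "date"], how="outer", indicator=True
    )
    n = merged["n_samples_0p1hz"].fillna(0).to_numpy()
    complete = merged["diary_complete"].eq(True).to_numpy()
    merged["valid_day"] = (n >= min_samples) & complete
    merged = merged.drop(columns="_merge")
    return merged


def compliance_filter(
    days: pd.DataFrame,
    min_valid_days: int = MIN_VALID_DAYS,
    valid_col: str = "valid_day",
) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Drop participants with fewer than ``min_valid_days`` valid days.

    Returns the retained table (valid days of compliant participants) and a
    flow report.  Raises if no participant survives.
    """
    if valid_col not in days.columns:
        raise ValueError(f"column {valid_col!r} missing; run mark_valid_days first")
    n_pid_in = days["participant_id"].nunique()
    n_days_in = len(days)
    valid = days[days[valid_col].astype(bool)]
    counts = valid.groupby("participant_id").size()
    keep_pids = set(counts[counts >= min_valid_days].index)
    kept = valid[valid["participant_id"].isin(keep_pids)].copy()
    report = CohortFilterReport(
        n_participants_in=n_pid_in,
        n_participants_out=len(keep_pids),
        n_days_in=n_days_in,
        n_days_out=len(kept),
        exclusions={
            "invalid_days": int(n_days_in - len(valid)),
            "noncompliant_participants": int(n_pid_in - len(keep_pids)),
            "days_of_noncompliant_participants": int(len(valid) - len(kept)),
        },
    )
    if kept.empty:
        raise ValueError("no participants left after the compliance filter")
    return kept.reset_index(drop=True), report


def read_diary_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_diary_csv(diary: pd.DataFrame, path) -> None:
    cols = [c for c in DIARY_COLUMNS if c in diary.columns]
    diary.to_csv(path, index=False, columns=cols)
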