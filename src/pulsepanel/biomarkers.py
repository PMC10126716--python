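"""Daily autonomic biomarkers from preprocessed 0.1 Hz heart-rate series.

Two heart-rate characteristics are computed per participant-day:

* **resting heart rate** — the minimum over the day of a 5-minute rolling
  mean (30 samples at 0.1 Hz), using fully observed windows only; elevated
  values indicate sympathetic dominance.
* **sample entropy** (SampEn, Richman–Moorman) — ``−ln(A/B)`` where B counts
  pairs of length-m templates and A pairs of length-(m+1) templates whose
  Chebyshev distance is within a tolerance r; higher values mean a more
  irregular, adaptive heart-rate signal.  m = 2; r is individualized as
  0.15 × the SD of all of a participant's heart-rate samples; only the first
  6 h of data per day (2160 samples at 0.1 Hz) enter, so that series length
  does not confound the estimate.

The module also computes daily minutes of moderate-to-vigorous physical
activity (time above 40% heart-rate reserve) and the within-participant
Tukey-fence outlier filter applied to the daily biomarker series.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .series import HeartRateSeries

ENTROPY_WINDOW_SAMPLES = 2160  # 6 h at 0.1 Hz
RESTING_WINDOW_S = 300.0  # 5 min
DEFAULT_MVPA_FRACTION = 0.40
IQR_MULTIPLIER = 1.5

BIOMARKER_COLUMNS = [
    "participant_id", "date", "resting_hr", "sample_entropy", "mvpa_minutes",
    "n_samples_0p1hz", "valid_hr_day", "outlier_rhr", "outlier_sampen",
]


@dataclasses.dataclass
class EntropyParams:
    """Sample-entropy settings: embedding dimension m, tolerance multiplier,
    and the fixed analysis window length in samples."""

    m: int = 2
    r_coefficient: float = 0.15
    window_samples: int = ENTROPY_WINDOW_SAMPLES

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_coefficient <= 0:
            raise ValueError("r_coefficient must be > 0")
        if self.window_samples <= self.m + 1:
            raise ValueError("window_samples must exceed m + 1")


@dataclasses.dataclass
class DailyBiomarkers:
    """Derived biomarkers for one participant-day."""

    participant_id: str
    date: dt.date
    resting_hr: float
    sample_entropy: float
    mvpa_minutes: float
    n_samples_0p1hz: int
    valid_hr_day: bool = False
    outlier_rhr: bool = False
    outlier_sampen: bool = False


def resting_heart_rate(series: HeartRateSeries, window_s: float = RESTING_WINDOW_S) -> float:
    """Minimum over fully observed 5-minute windows of the window mean.

    Windows are runs of consecutive bins; any missing sample invalidates the
    window (sparse windows would otherwise produce artificially low means).
    Returns NaN when no fully observed window exists.
    """
    w = int(round(window_s * series.rate_hz))
    if len(series) < w:
        return float("nan")
    means = pd.Series(series.hr).rolling(w, min_periods=w).mean().to_numpy()
    if not np.any(np.isfinite(means)):
        return float("nan")
    return float(np.nanmin(means))


def individual_tolerance(
    pooled_values: Iterable[float], r_coefficient: float = 0.15
) -> float:
    """Tolerance r = coefficient × SD of all of a participant's 0.1 Hz samples.

    The SD is the population SD (divisor N) over every non-missing sample of
    the participant's full study period.  A constant record has zero SD and
    no usable tolerance.
    """
    x = np.asarray(list(pooled_values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 non-missing samples to derive a tolerance")
    sd = float(np.std(x))  # ddof=0
    if sd == 0.0:
        raise ValueError(
            "pooled heart-rate SD is zero (constant record); sample entropy is "
            "undefined for this participant — check the input series"
        )
    return r_coefficient * sd


def sample_entropy_core(x: np.ndarray, m: int, r: float) -> float:
    """SampEn(m, r) of a 1-D series: −ln(A/B) with Richman–Moorman counts.

    B counts unordered template pairs i<j (self-matches excluded) whose
    length-m templates are within Chebyshev distance r; A is the analogous
    count for length-(m+1) templates.  Both counts run over the same N−m
    template start positions.  Returns NaN when A or B is zero (entropy
    undefined).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m  # template count shared by both lengths
    if nt < 2:
        return float("nan")
    diff = np.abs(x[:, None] - x[None, :]) <= r
    match = diff[:nt, :nt].copy()
    for k in range(1, m):
        match &= diff[k : k + nt, k : k + nt]
    b_count = (int(match.sum(dtype=np.int64)) - nt) // 2
    match &= diff[m : m + nt, m : m + nt]
    a_count = (int(match.sum(dtype=np.int64)) - nt) // 2
    if a_count == 0 or b_count == 0:
        return float("nan")
    return -math.log(a_count / b_count)


def sample_entropy(
    series: HeartRateSeries, params: EntropyParams, r: float
) -> float:
    """Daily sample entropy over the first 6 h of heart-rate data.

    The day's non-missing 0.1 Hz samples, in time order, are truncated to the
    first ``params.window_samples`` (2160); days with fewer samples yield a
    missing value, so every computed entropy uses an identical series length.
    """
    x = series.hr[np.isfinite(series.hr)]
    if x.size < params.window_samples:
        return float("nan")
    return sample_entropy_core(x[: params.window_samples], params.m, r)


def mvpa_minutes(
    series: HeartRateSeries,
    resting_hr: float,
    max_hr: float,
    fraction: float = DEFAULT_MVPA_FRACTION,
) -> float:
    """Minutes above the heart-rate-reserve intensity threshold.

    threshold = resting + (max − resting) × fraction; each non-missing 0.1 Hz
    sample strictly above it contributes 10 s.
    """
    if not np.isfinite(resting_hr):
        return float("nan")
    if max_hr <= resting_hr:
        raise ValueError("max_hr must exceed resting_hr for a heart-rate reserve")
    threshold = resting_hr + (max_hr - resting_hr) * fraction
    hr = series.hr
    above = int(np.sum(hr[np.isfinite(hr)] > threshold))
    return above * (series.dt_s / 60.0)


def max_hr_from_age(age: float) -> float:
    """Age-predicted maximal heart rate, 220 − age."""
    return 220.0 - float(age)


def remove_outliers(
    values: Iterable[float], k: float = IQR_MULTIPLIER
) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence filter on a participant's daily biomarker values.

    Values outside [Q1 − k·IQR, Q3 + k·IQR] (quartiles by linear interpolation
    of order statistics) are flagged; fewer than 4 non-missing values → no
    filtering.  Returns ``(values_with_outliers_set_to_nan, outlier_flags)``;
    missing inputs are never flagged.
    """
    x = np.asarray(list(values), dtype=float)
    flags = np.zeros(x.shape, dtype=bool)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        return x.copy(), flags
    q1, q3 = np.percentile(x[finite], [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags[finite] = (x[finite] < lo) | (x[finite] > hi)
    out = x.copy()
    out[flags] = np.nan
    return out, flags


def compute_daily_biomarkers(
    day_series: Iterable[HeartRateSeries],
    participant_age: Mapping[str, float] | None = None,
    entropy_params: EntropyParams | None = None,
    mvpa_fraction: float = DEFAULT_MVPA_FRACTION,
    max_hr_rule: str = "220_minus_age",
    min_samples: int = ENTROPY_WINDOW_SAMPLES,
    iqr_multiplier: float = IQR_MULTIPLIER,
) -> pd.DataFrame:
    """Full biomarker table from preprocessed 0.1 Hz day series.

    Two passes per participant: the pooled SD over the whole study period
    fixes the entropy tolerance first, then each day yields resting HR,
    sample entropy, and MVPA minutes.  The within-participant outlier filter
    is applied to the resting-HR and entropy columns; flagged values are kept
    in the table (flag columns) and excluded later at design-building time.

    ``max_hr_rule`` is either ``"220_minus_age"`` (requires ``participant_age``)
    or ``"observed_max"`` (participant's maximum preprocessed sample).
    """
    params = entropy_params or EntropyParams()
    by_pid: dict[str, list[HeartRateSeries]] = {}
    for s in day_series:
        by_pid.setdefault(s.participant_id, []).append(s)

    rows: list[dict] = []
    for pid in sorted(by_pid):
        days = sorted(by_pid[pid], key=lambda s: s.date)
        pooled = np.concatenate([d.hr[np.isfinite(d.hr)] for d in days])
        try:
            r = individual_tolerance(pooled, params.r_coefficient)
        except ValueError:
            r = float("nan")
        if max_hr_rule == "observed_max":
            max_hr = float(pooled.max()) if pooled.size else float("nan")
        elif max_hr_rule == "220_minus_age":
            if participant_age is None or pid not in participant_age:
                raise ValueError(f"age needed for max-HR rule but missing for {pid!r}")
            max_hr = max_hr_from_age(participant_age[pid])
        else:
            raise ValueError(f"unknown max_hr_rule {max_hr_rule!r}")
        for d in days:
            rhr = resting_heart_rate(d)
            ent = (
                sample_entropy(d, params, r) if np.isfinite(r) else float("nan")
            )
            if np.isfinite(rhr) and max_hr > rhr:
                mvpa = mvpa_minutes(d, rhr, max_hr, mvpa_fraction)
            else:
                mvpa = float("nan")
            n_valid = d.n_valid
            rows.append(
                {
                    "participant_id": pid,
                    "date": d.date,
                    "resting_hr": rhr,
                    "sample_entropy": ent,
                    "mvpa_minutes": mvpa,
                    "n_samples_0p1hz": n_valid,
                    "valid_hr_day": n_valid >= min_samples,
                }
            )
    df = pd.DataFrame(rows, columns=BIOMARKER_COLUMNS[:7])
    for metric, flag in [("resting_hr", "outlier_rhr"), ("sample_entropy", "outlier_sampen")]:
        flags = np.zeros(len(df), dtype=bool)
        for pid, g in df.groupby("participant_id"):
            _, f = remove_outliers(g[metric].to_numpy(), k=iqr_multiplier)
            flags[g.index.to_numpy()] = f
        df[flag] = flags
    return df
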