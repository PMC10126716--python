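"""Time-stamped heart-rate series for one participant-day, plus CSV I/O.

A wrist-worn optical sensor reports one beats-per-minute sample per second
during waking hours.  Gaps (watch off, Bluetooth dropouts) appear as missing
samples.  Internally a series lives on a regular grid at its nominal rate,
with ``NaN`` marking missing samples, so that gap lengths are simply run
lengths.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

RAW_RATE_HZ = 1.0
DOWNSAMPLED_RATE_HZ = 0.1
HR_MIN_BPM = 25.0
HR_MAX_BPM = 250.0

HR_CSV_COLUMNS = ["participant_id", "date", "timestamp_s", "hr_bpm"]


@dataclasses.dataclass
class HeartRateSeries:
    """Heart-rate samples for one participant on one calendar day.

    Parameters
    ----------
    participant_id : str
        Cohort identifier of the wearer.
    date : datetime.date
        Calendar day the samples belong to.
    t : ndarray of float
        Sample timestamps in seconds since midnight, strictly increasing,
        regularly spaced at ``1 / rate_hz``.
    hr : ndarray of float
        Heart rate in beats per minute; ``NaN`` marks a missing sample.
        Non-missing values must lie in [25, 250] bpm.
    rate_hz : float
        Nominal sampling frequency: 1.0 for raw device output, 0.1 after
        downsampling.
    """

    participant_id: str
    date: dt.date
    t: np.ndarray
    hr: np.ndarray
    rate_hz: float = RAW_RATE_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.t.ndim != 1 or self.hr.ndim != 1 or len(self.t) != len(self.hr):
            raise ValueError("t and hr must be 1-D arrays of equal length")
        if len(self.t) == 0:
            raise ValueError("empty heart-rate series")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("timestamps must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        finite = self.hr[np.isfinite(self.hr)]
        if finite.size and (finite.min() < HR_MIN_BPM or finite.max() > HR_MAX_BPM):
            raise ValueError(
                f"heart-rate values outside [{HR_MIN_BPM}, {HR_MAX_BPM}] bpm"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        """Number of non-missing samples."""
        return int(np.sum(np.isfinite(self.hr)))

    @property
    def dt_s(self) -> float:
        """Nominal sampling interval in seconds."""
        return 1.0 / self.rate_hz

    def is_regular(self, tol: float = 1e-9) -> bool:
        """True if timestamps sit on a uniform grid at the nominal rate."""
        if len(self.t) == 1:
            return True
        return bool(np.allclose(np.diff(self.t), self.dt_s, atol=tol))

    def replace(self, **kwargs) -> "HeartRateSeries":
        return dataclasses.replace(self, **kwargs)


def from_observations(
    participant_id: str,
    date: dt.date,
    t_obs: Iterable[float],
    hr_obs: Iterable[float],
    rate_hz: float = RAW_RATE_HZ,
) -> HeartRateSeries:
    """Build a regular-grid series from (possibly gappy) observations.

    The grid spans from the first to the last observed timestamp at the
    nominal rate; timestamps without an observation become ``NaN``.
    """
    t_obs = np.asarray(list(t_obs), dtype=float)
    hr_obs = np.asarray(list(hr_obs), dtype=float)
    if t_obs.size == 0:
        raise ValueError("no observations")
    order = np.argsort(t_obs)
    t_obs, hr_obs = t_obs[order], hr_obs[order]
    step = 1.0 / rate_hz
    idx = np.round((t_obs - t_obs[0]) / step).astype(int)
    if np.any(np.diff(idx) < 1):
        raise ValueError("duplicate timestamps after snapping to the grid")
    n = idx[-1] + 1
    t = t_obs[0] + step * np.arange(n)
    hr = np.full(n, np.nan)
    hr[idx] = hr_obs
    return HeartRateSeries(participant_id, date, t, hr, rate_hz)


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def to_frame(series_iter: Iterable[HeartRateSeries], drop_missing: bool = False) -> pd.DataFrame:
    """Concatenate series into the long CSV layout (empty field = missing)."""
    chunks = []
    for s in series_iter:
        chunks.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "date": s.date.isoformat(),
                    "timestamp_s": s.t,
                    "hr_bpm": s.hr,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=HR_CSV_COLUMNS)
    out = pd.concat(chunks, ignore_index=True)
    if drop_missing:
        out = out[np.isfinite(out["hr_bpm"])].reset_index(drop=True)
    return out


def write_hr_csv(series_iter: Iterable[HeartRateSeries], path) -> None:
    """Write series to a long-format CSV: participant_id,date,timestamp_s,hr_bpm."""
    to_frame(series_iter).to_csv(path, index=False)


def read_hr_csv(path, rate_hz: float | None = None) -> list[HeartRateSeries]:
    """Read a long-format heart-rate CSV into one series per participant-day.

    Rows with an empty ``hr_bpm`` field are missing samples; absent timestamps
    are also treated as missing (the grid is re-derived from the first and
    last timestamp of each day).  ``rate_hz`` defaults to 1 Hz raw data; pass
    0.1 for preprocessed files.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in HR_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"heart-rate CSV missing columns: {missing}")
    rate = RAW_RATE_HZ if rate_hz is None else rate_hz
    out: list[HeartRateSeries] = []
    for (pid, date), g in df.groupby(["participant_id", "date"], sort=True):
        keep = np.isfinite(g["hr_bpm"].to_numpy(dtype=float)) | True  # keep rows; NaN handled by grid
        g = g[keep]
        obs = g[np.isfinite(g["hr_bpm"].astype(float))]
        if len(obs) == 0:
            continue
        out.append(
            from_observations(
                str(pid), _parse_date(date),
                obs["timestamp_s"].to_numpy(dtype=float),
                obs["hr_bpm"].to_numpy(dtype=float),
                rate_hz=rate,
            )
        )
    return out


def iter_participant_days(
    series_list: Iterable[HeartRateSeries],
) -> Iterator[tuple[str, dt.date, HeartRateSeries]]:
    for s in series_list:
        yield s.participant_id, s.date, s
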