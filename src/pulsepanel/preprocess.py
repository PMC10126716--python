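"""Three-step preprocessing of raw 1 Hz daytime heart-rate series.

The chain reduces optical-sensor noise while preserving the intrinsic speed
of heart-rate dynamics:

1. :func:`interpolate_gaps` — linear interpolation of missing runs strictly
   shorter than 20 s; longer gaps and gaps touching the series edges stay
   missing.
2. :func:`lowess_smooth` — locally weighted scatterplot smoothing (tricube
   weights, local linear fit, zero robustness iterations) with a 60 s
   bandwidth, applied independently within each gap-free segment.
3. :func:`downsample` — centered means over consecutive 10 s bins, yielding a
   regular 0.1 Hz series.

:func:`preprocess_day` runs the three steps in this fixed order.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .series import DOWNSAMPLED_RATE_HZ, HeartRateSeries

DEFAULT_MAX_GAP_S = 20.0
DEFAULT_BANDWIDTH_S = 60.0
DEFAULT_BIN_S = 10.0


@dataclasses.dataclass
class PreprocessLog:
    """Per-day bookkeeping emitted by the preprocessing chain."""

    n_interpolated_samples: int = 0
    n_gaps_filled: int = 0
    n_gaps_left: int = 0
    n_segments_unsmoothed: int = 0
    n_output_bins: int = 0
    n_missing_bins: int = 0


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as half-open (start, stop) index pairs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def interpolate_gaps(
    series: HeartRateSeries,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    log: PreprocessLog | None = None,
) -> tuple[HeartRateSeries, PreprocessLog]:
    """Fill missing runs strictly shorter than ``max_gap_s`` by linear interpolation.

    A run of k consecutive missing samples at rate f spans k/f seconds; it is
    filled iff that span is < ``max_gap_s`` and it has non-missing flanking
    samples on both sides (edge gaps are never filled).

    Raises
    ------
    ValueError
        If fewer than two non-missing samples exist (nothing to interpolate
        between).
    """
    log = log if log is not None else PreprocessLog()
    hr = series.hr.copy()
    miss = ~np.isfinite(hr)
    valid_idx = np.flatnonzero(~miss)
    if valid_idx.size < 2:
        raise ValueError("need at least 2 non-missing samples to interpolate")
    n = len(hr)
    fill_positions: list[np.ndarray] = []
    for start, stop in _nan_runs(miss):
        interior = start > 0 and stop < n
        span_s = (stop - start) * series.dt_s
        if interior and span_s < max_gap_s:
            fill_positions.append(np.arange(start, stop))
            log.n_gaps_filled += 1
        else:
            log.n_gaps_left += 1
    if fill_positions:
        pos = np.concatenate(fill_positions)
        hr[pos] = np.interp(series.t[pos], series.t[valid_idx], hr[valid_idx])
        log.n_interpolated_samples += int(pos.size)
    return series.replace(hr=hr), log


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _local_linear_fit(t: np.ndarray, y: np.ndarray, t0: float, half_bw: float) -> float:
    """Tricube-weighted local linear fit evaluated at t0 (one point)."""
    d = t - t0
    w = _tricube(d / half_bw)
    sw = w.sum()
    swd = (w * d).sum()
    swdd = (w * d * d).sum()
    swy = (w * y).sum()
    swdy = (w * d * y).sum()
    denom = sw * swdd - swd * swd
    if denom <= 0 or not np.isfinite(denom):
        return swy / sw  # degenerate spread: weighted mean
    return (swy * swdd - swd * swdy) / denom


def _lowess_segment(t: np.ndarray, y: np.ndarray, half_bw: float, dt_s: float) -> np.ndarray:
    """LOWESS one gap-free segment; fast convolution path on the regular grid.

    Interior points with a full, symmetric window reduce to a fixed-kernel
    weighted mean (the slope term of the local linear fit vanishes by
    symmetry); edge points get an explicit weighted linear fit.
    """
    n = len(y)
    h = int(np.floor(half_bw / dt_s))  # samples on each side inside the window
    out = np.empty(n)
    if n >= 2 * h + 1 and h >= 1:
        kernel = _tricube(np.arange(-h, h + 1) * dt_s / half_bw)
        kernel = kernel / kernel.sum()
        out[h : n - h] = np.convolve(y, kernel[::-1], mode="valid")
        edge = list(range(h)) + list(range(n - h, n))
    else:
        edge = list(range(n))
    for i in edge:
        lo = np.searchsorted(t, t[i] - half_bw, side="left")
        hi = np.searchsorted(t, t[i] + half_bw, side="right")
        out[i] = _local_linear_fit(t[lo:hi], y[lo:hi], t[i], half_bw)
    return out


def lowess_smooth(
    series: HeartRateSeries,
    bandwidth_s: float = DEFAULT_BANDWIDTH_S,
    log: PreprocessLog | None = None,
) -> HeartRateSeries:
    """Smooth each contiguous non-missing segment with tricube local linear fits.

    The window at a point covers samples within ±``bandwidth_s``/2 of its
    timestamp.  Segments with fewer than 3 samples are passed through
    unsmoothed (counted in the log).  Missing samples stay missing; long gaps
    therefore break the smoother — it never bridges disconnected data.
    """
    half_bw = bandwidth_s / 2.0
    hr = series.hr.copy()
    miss = ~np.isfinite(hr)
    for start, stop in _nan_runs(~miss):  # runs of valid samples
        seg = slice(start, stop)
        if stop - start < 3:
            if log is not None:
                log.n_segments_unsmoothed += 1
            continue
        hr[seg] = _lowess_segment(series.t[seg], series.hr[seg], half_bw, series.dt_s)
    np.clip(hr, 25.0, 250.0, out=hr)
    return series.replace(hr=hr)


def downsample(
    series: HeartRateSeries,
    bin_s: float = DEFAULT_BIN_S,
    log: PreprocessLog | None = None,
) -> HeartRateSeries:
    """Centered means over consecutive half-open ``bin_s`` bins.

    Bins are anchored at the first sample's timestamp (data-relative, not
    midnight-relative): bin k covers [t0 + k·bin_s, t0 + (k+1)·bin_s) and its
    output sample is stamped at the bin center t0 + (k + 1/2)·bin_s.  Bins
    with no non-missing sample yield a missing output sample.
    """
    t0 = series.t[0]
    k = np.floor((series.t - t0) / bin_s + 1e-9).astype(int)
    n_bins = k[-1] + 1
    finite = np.isfinite(series.hr)
    sums = np.bincount(k[finite], weights=series.hr[finite], minlength=n_bins)
    counts = np.bincount(k[finite], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    t_out = t0 + (np.arange(n_bins) + 0.5) * bin_s
    if log is not None:
        log.n_output_bins = int(n_bins)
        log.n_missing_bins = int(np.sum(counts == 0))
    return series.replace(t=t_out, hr=values, rate_hz=1.0 / bin_s)


def preprocess_day(
    series: HeartRateSeries,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    bandwidth_s: float = DEFAULT_BANDWIDTH_S,
    bin_s: float = DEFAULT_BIN_S,
) -> tuple[HeartRateSeries, PreprocessLog]:
    """Run interpolate → smooth → downsample in the mandated order."""
    log = PreprocessLog()
    filled, log = interpolate_gaps(series, max_gap_s=max_gap_s, log=log)
    smooth = lowess_smooth(filled, bandwidth_s=bandwidth_s, log=log)
    out = downsample(smooth, bin_s=bin_s, log=log)
    return out, log
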