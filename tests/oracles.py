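"""Independent reference implementations used as test oracles.

Everything here is deliberately straightforward and structurally different
from the package's optimized code paths: explicit scans and per-point fits
instead of vectorized convolutions, template matrices instead of shifted
distance-matrix ANDs, one dense covariance matrix instead of grouped
Cholesky factorizations.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np

from pulsepanel.series import HeartRateSeries


# ---------------------------------------------------------------------------
# sample entropy: template-matrix brute force
# ---------------------------------------------------------------------------

def brute_sample_entropy(x, m: int, r: float) -> float:
    """O(N^2) SampEn via explicit template matrices and row-wise distances."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m
    if nt < 2:
        return float("nan")
    tm = np.array([x[i : i + m] for i in range(nt)])
    tm1 = np.array([x[i : i + m + 1] for i in range(nt)])
    b = a = 0
    for i in range(nt - 1):
        db = np.max(np.abs(tm[i + 1 :] - tm[i]), axis=1)
        da = np.max(np.abs(tm1[i + 1 :] - tm1[i]), axis=1)
        b += int(np.sum(db <= r))
        a += int(np.sum(da <= r))
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


# ---------------------------------------------------------------------------
# preprocessing: unoptimized scan-based chain
# ---------------------------------------------------------------------------

def naive_interpolate(t, hr, max_gap_s=20.0, dt_s=1.0):
    hr = np.asarray(hr, dtype=float).copy()
    t = np.asarray(t, dtype=float)
    n = len(hr)
    i = 0
    while i < n:
        if not np.isnan(hr[i]):
            i += 1
            continue
        j = i
        while j < n and np.isnan(hr[j]):
            j += 1
        if i > 0 and j < n and (j - i) * dt_s < max_gap_s:
            t0, t1, y0, y1 = t[i - 1], t[j], hr[i - 1], hr[j]
            for k in range(i, j):
                hr[k] = y0 + (y1 - y0) * (t[k] - t0) / (t1 - t0)
        i = j
    return hr


def naive_lowess(t, hr, bandwidth_s=60.0):
    t = np.asarray(t, dtype=float)
    hr = np.asarray(hr, dtype=float)
    out = hr.copy()
    half = bandwidth_s / 2.0
    n = len(hr)
    i = 0
    while i < n:
        if np.isnan(hr[i]):
            i += 1
            continue
        j = i
        while j < n and not np.isnan(hr[j]):
            j += 1
        if j - i >= 3:
            ts, ys = t[i:j], hr[i:j]
            for k in range(i, j):
                d = ts - t[k]
                inside = np.abs(d) <= half
                w = np.clip(1.0 - np.abs(d[inside] / half) ** 3, 0.0, None) ** 3
                design = np.column_stack([np.ones(inside.sum()), d[inside]])
                sw = np.sqrt(w)
                coef, *_ = np.linalg.lstsq(design * sw[:, None], ys[inside] * sw, rcond=None)
                out[k] = coef[0]
        i = j
    return np.clip(out, 25.0, 250.0)


def naive_downsample(t, hr, bin_s=10.0):
    t = np.asarray(t, dtype=float)
    hr = np.asarray(hr, dtype=float)
    t0 = t[0]
    n_bins = int(np.floor((t[-1] - t0) / bin_s)) + 1
    t_out = np.empty(n_bins)
    v_out = np.empty(n_bins)
    for k in range(n_bins):
        lo, hi = t0 + k * bin_s, t0 + (k + 1) * bin_s
        sel = (t >= lo) & (t < hi) & ~np.isnan(hr)
        v_out[k] = hr[sel].mean() if sel.any() else np.nan
        t_out[k] = t0 + (k + 0.5) * bin_s
    return t_out, v_out


def naive_preprocess_chain(t, hr, max_gap_s=20.0, bandwidth_s=60.0, bin_s=10.0, dt_s=1.0):
    filled = naive_interpolate(t, hr, max_gap_s, dt_s)
    smooth = naive_lowess(t, filled, bandwidth_s)
    return naive_downsample(t, smooth, bin_s)


def random_raw_day(
    rng: np.random.Generator,
    n_seconds: int = 1800,
    pid: str = "P0",
    date: dt.date = dt.date(2017, 3, 1),
) -> HeartRateSeries:
    """A gappy, noisy, drifting 1 Hz day for oracle cross-checks."""
    t = np.arange(n_seconds, dtype=float)
    hr = (
        70.0
        + 8.0 * np.sin(2 * np.pi * t / 900.0)
        + rng.normal(0.0, 3.0, n_seconds)
    )
    n_gaps = rng.poisson(n_seconds / 300.0)
    for _ in range(n_gaps):
        g0 = int(rng.integers(0, n_seconds))
        glen = int(rng.integers(2, 40))
        hr[g0 : g0 + glen] = np.nan
    hr = np.clip(hr, 30.0, 240.0)
    if not np.isfinite(hr[0]):
        hr[0] = 70.0
    if not np.isfinite(hr[-1]):
        hr[-1] = 70.0
    return HeartRateSeries(pid, date, t, hr, rate_hz=1.0)


# ---------------------------------------------------------------------------
# REML: single dense covariance matrix
# ---------------------------------------------------------------------------

def dense_reml_loglik(y, X, pids, days, sigma_b2, sigma2, rho):
    """Restricted log-likelihood by explicit marginal-covariance assembly."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    pids = np.asarray(pids)
    days = np.asarray(days, dtype=int)
    n, p = X.shape
    V = np.zeros((n, n))
    for pid in np.unique(pids):
        sel = np.where(pids == pid)[0]
        d = days[sel]
        if rho == 0.0:
            R = np.eye(len(d))
        else:
            R = np.power(float(rho), np.abs(d[:, None] - d[None, :]))
        V[np.ix_(sel, sel)] = sigma_b2 + sigma2 * R
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    _, logdet_v = np.linalg.slogdet(V)
    _, logdet_x = np.linalg.slogdet(XtViX)
    quad = float(resid @ Vi @ resid)
    return -0.5 * ((n - p) * math.log(2 * math.pi) + logdet_v + logdet_x + quad)
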