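"""Distributed-lag linear mixed models with AR(1) residuals.

The analysis panel couples a daily autonomic outcome (resting heart rate or
heart-rate sample entropy) with daily allergy-burden exposures (symptom
score, mood) at lags 0, 1 and 2 days, plus an adjustment set of participant
and calendar covariates.  The estimating model for participant i on day d is

    y_id = x_id' beta + b_i + eps_id,
    b_i ~ N(0, sigma_b^2),
    Corr(eps_id, eps_id') = rho^{|d - d'|},  Var(eps_id) = sigma^2,

i.e. a random intercept per participant with first-order autoregressive
residual correlation that decays with *calendar-day* distance, so a gap of
Delta days carries correlation rho^Delta.  Estimation is by restricted
maximum likelihood (REML): the fixed effects are profiled out by generalized
least squares given the variance parameters, the residual variance is
profiled analytically, and the remaining two parameters (variance ratio
gamma = sigma_b^2/sigma^2 and rho) are optimized on transformed scales
(log gamma, atanh rho) from multiple starts.  Confidence intervals are Wald:
beta +/- 1.96 se.

Also here: the a-priori sample-size computation for an F-test of an R^2
increase (Cohen's f^2 effect size, noncentral-F power).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats

from .diary import MED_CLASSES, SYMPTOM_ITEMS

Z_95 = 1.96

#: Adjustment covariates mirroring the study design (month enters separately
#: as one-hot dummies with the first study month as reference).
ADJUSTMENT_COVARIATES = (
    "age",
    "sex_female",
    "allergy_grass_dust",
    "mvpa_minutes",
    "no2",
    "pm10",
    "med_antihistamine",
    "med_corticosteroid",
    "med_decongestant",
    "weekend",
    "season_birch",
    "season_alder",
    "season_hazel",
)

OUTCOMES = ("resting_hr", "sample_entropy")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``exposures`` may be the composite ``symptom_score``, ``mood``, both
    (multi-exposure), or a single symptom item (post-hoc models).  ``lags``
    is the distributed-lag set {0,1,2} or a single lag for sensitivity fits.
    """

    outcome: str
    exposures: tuple[str, ...]
    lags: tuple[int, ...] = (0, 1, 2)
    adjust: tuple[str, ...] = ADJUSTMENT_COVARIATES
    month_dummies: bool = True

    def __post_init__(self) -> None:
        if not self.lags:
            raise ValueError("lag set must be nonempty")
        if any(l not in (0, 1, 2) for l in self.lags):
            raise ValueError("lags must lie in {0, 1, 2}")
        if not self.exposures:
            raise ValueError("at least one exposure required")

    @property
    def lag_terms(self) -> list[str]:
        return [f"{e}_lag{l}" for e in self.exposures for l in self.lags]


@dataclasses.dataclass
class ModelFrame:
    """Analysis-ready panel: outcome + design columns, no missing cells."""

    data: pd.DataFrame
    outcome: str
    terms: list[str]
    spec: ModelSpec | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        used = [self.outcome] + self.terms
        if self.data[used].isna().any().any():
            raise ValueError("ModelFrame contains missing cells")

    @property
    def y(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy(dtype=float)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.terms].to_numpy(dtype=float)

    @property
    def pids(self) -> np.ndarray:
        return self.data["participant_id"].to_numpy()

    @property
    def days(self) -> np.ndarray:
        return self.data["day_index"].to_numpy(dtype=int)

    @property
    def n_participants(self) -> int:
        return int(self.data["participant_id"].nunique())


@dataclasses.dataclass
class FitResult:
    """REML fit: fixed effects with Wald CIs plus variance components."""

    beta: pd.Series
    se: pd.Series
    sigma_b2: float
    sigma2: float
    rho: float
    loglik: float
    n_obs: int
    n_participants: int
    converged: bool
    outcome: str = ""

    @property
    def ci95(self) -> pd.DataFrame:
        lo = self.beta - Z_95 * self.se
        hi = self.beta + Z_95 * self.se
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.beta, "se": self.se})
        out["ci_low"] = out["estimate"] - Z_95 * out["se"]
        out["ci_high"] = out["estimate"] + Z_95 * out["se"]
        return out


# ---------------------------------------------------------------------------
# design building
# ---------------------------------------------------------------------------

def _as_ts(dates: pd.Series) -> pd.Series:
    return pd.to_datetime(dates)


def make_model_frame(
    panel: pd.DataFrame,
    spec: ModelSpec,
    exposure_source: pd.DataFrame | None = None,
) -> ModelFrame:
    """Assemble a :class:`ModelFrame` from a daily panel.

    Lag-l exposure for calendar day d is the value reported on day d-l
    (calendar alignment — a skipped diary day breaks the lag, regardless of
    row order).  ``exposure_source`` defaults to the panel itself; the full
    pipeline passes the raw scored diary so lags may come from days that are
    themselves invalid as outcome days.  Rows with any missing outcome, lag
    or covariate are dropped (and counted).
    """
    df = panel.copy()
    df["_date"] = _as_ts(df["date"])
    source = exposure_source if exposure_source is not None else panel
    src = source.copy()
    src["_date"] = _as_ts(src["date"])

    missing_cols = [e for e in spec.exposures if e not in src.columns]
    missing_cols += [c for c in (spec.outcome, *spec.adjust) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"spec references absent columns: {sorted(set(missing_cols))}")

    for e in spec.exposures:
        for lag in spec.lags:
            lookup = src[["participant_id", "_date", e]].copy()
            lookup["_date"] = lookup["_date"] + pd.Timedelta(days=lag)
            lookup = lookup.rename(columns={e: f"{e}_lag{lag}"})
            lookup = lookup.drop_duplicates(subset=["participant_id", "_date"])
            df = df.merge(lookup, on=["participant_id", "_date"], how="left")

    terms = ["const"] + spec.lag_terms + list(spec.adjust)
    df["const"] = 1.0
    if spec.month_dummies:
        months = df["_date"].dt.month
        ref_month = int(df.loc[df["_date"].idxmin(), "_date"].month)
        for m in sorted(months.unique()):
            if m == ref_month:
                continue
            name = f"month_{int(m):02d}"
            df[name] = (months == m).astype(float)
            terms.append(name)

    used = [spec.outcome] + terms
    keep = df[used].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    df = df[keep].copy()
    if df.empty:
        raise ValueError("no complete rows left after lagging and adjustment")
    # adjustment columns that are constant (e.g. a medication class nobody
    # took) or aliased with other covariates (small cohorts can have fewer
    # participants than participant-level covariates) carry no estimable
    # information; prune them, never touching the intercept or exposure terms
    protected = ["const"] + spec.lag_terms
    degenerate = [
        t for t in terms if t not in protected and df[t].nunique() <= 1
    ]
    terms = [t for t in terms if t not in degenerate]
    X = df[terms].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < len(terms):
        # keep the intercept and exposure terms; greedily retain each
        # adjustment column only if it adds rank (R-style aliased-term drop)
        base = df[protected].to_numpy(dtype=float)
        if np.linalg.matrix_rank(base) < len(protected):
            raise ValueError(
                f"singular design matrix; collinear exposure terms: {protected}"
            )
        kept = list(protected)
        for t in terms:
            if t in protected:
                continue
            trial = df[kept + [t]].to_numpy(dtype=float)
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(t)
        terms = [t for t in terms if t in kept]
    df["day_index"] = (
        df["_date"].map(pd.Timestamp.toordinal) - df["_date"].map(pd.Timestamp.toordinal).min()
    ).astype(int)
    df = df.sort_values(["participant_id", "day_index"]).reset_index(drop=True)
    cols = ["participant_id", "date", "day_index", spec.outcome] + terms
    return ModelFrame(df[cols], spec.outcome, terms, spec=spec, n_dropped=n_dropped)


def build_design(
    biomarkers: pd.DataFrame,
    diary: pd.DataFrame,
    participants: pd.DataFrame,
    calendar: pd.DataFrame,
    spec: ModelSpec,
    min_samples: int | None = None,
    min_valid_days: int | None = None,
    apply_filters: bool = True,
):
    """Full design build from the four pipeline tables.

    Applies, in order: diary scoring, valid-day marking, the compliance
    filter, exclusion of outlier-flagged outcome values, covariate merges,
    calendar-aligned lagging.  Returns ``(ModelFrame, CohortFilterReport)``.
    """
    from .biomarkers import ENTROPY_WINDOW_SAMPLES
    from .diary import MIN_VALID_DAYS, compliance_filter, mark_valid_days, score_diary

    scored = score_diary(diary)
    merged = mark_valid_days(
        biomarkers, scored,
        min_samples=ENTROPY_WINDOW_SAMPLES if min_samples is None else min_samples,
    )
    report = None
    if apply_filters:
        merged, report = compliance_filter(
            merged, MIN_VALID_DAYS if min_valid_days is None else min_valid_days
        )
    outlier_col = {"resting_hr": "outlier_rhr", "sample_entropy": "outlier_sampen"}.get(spec.outcome)
    if outlier_col and outlier_col in merged.columns:
        flagged = merged[outlier_col].eq(True)
        merged.loc[flagged, spec.outcome] = np.nan

    panel = merged.merge(participants, on="participant_id", how="left")
    cal = calendar.copy()
    panel["_d"] = _as_ts(panel["date"])
    cal["_d"] = _as_ts(cal["date"])
    panel = panel.merge(cal.drop(columns=["date"]), on="_d", how="left").drop(columns=["_d"])
    frame = make_model_frame(panel, spec, exposure_source=scored)
    return frame, report


# ---------------------------------------------------------------------------
# REML estimation
# ---------------------------------------------------------------------------

def _grouped_data(y: np.ndarray, X: np.ndarray, pids: np.ndarray, days: np.ndarray):
    """Group participants by their day-spacing pattern for batched solves."""
    order = np.lexsort((days, pids))
    y, X, pids, days = y[order], X[order], pids[order], days[order]
    groups: dict[tuple, dict] = {}
    for pid in pd.unique(pids):
        sel = pids == pid
        d = days[sel]
        key = tuple(np.diff(d))
        g = groups.setdefault(key, {"D": None, "Y": [], "X": []})
        if g["D"] is None:
            g["D"] = np.abs(d[:, None] - d[None, :])
        g["Y"].append(y[sel])
        g["X"].append(X[sel])
    out = []
    for g in groups.values():
        out.append(
            {
                "D": g["D"],
                "Y": np.stack(g["Y"]),            # (g, n)
                "X": np.stack(g["X"]),            # (g, n, p)
            }
        )
    return out


def _profiled_reml(gamma: float, rho: float, groups, n: int, p: int):
    """Negative twice the profiled restricted log-likelihood, plus GLS pieces.

    The marginal covariance per participant is sigma^2 * (gamma*J + R(rho))
    with R_jk = rho^{|d_j - d_k|}; sigma^2 is profiled analytically.
    """
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for grp in groups:
        D = grp["D"]
        ni = D.shape[0]
        if rho == 0.0:
            V = gamma * np.ones((ni, ni)) + np.eye(ni)
        else:
            V = gamma * np.ones((ni, ni)) + np.power(float(rho), D)
        try:
            L = sla.cholesky(V, lower=True)
        except sla.LinAlgError:
            return np.inf, None, None, None
        g = grp["Y"].shape[0]
        B = np.concatenate([grp["X"], grp["Y"][:, :, None]], axis=2)  # (g, ni, p+1)
        Bt = B.transpose(1, 0, 2).reshape(ni, g * (p + 1))
        S = sla.solve_triangular(L, Bt, lower=True)
        S = S.reshape(ni, g, p + 1).transpose(1, 0, 2)
        Xs, ys = S[:, :, :p], S[:, :, p]
        XtX += np.einsum("gni,gnj->ij", Xs, Xs)
        Xty += np.einsum("gni,gn->i", Xs, ys)
        yty += float(np.einsum("gn,gn->", ys, ys))
        logdet += 2.0 * g * float(np.sum(np.log(np.diag(L))))
    try:
        beta = sla.solve(XtX, Xty, assume_a="pos")
    except sla.LinAlgError:
        return np.inf, None, None, None
    rss = yty - float(Xty @ beta)
    dof = n - p
    if rss <= 0 or dof <= 0:
        return np.inf, None, None, None
    sigma2 = rss / dof
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    if sign <= 0:
        return np.inf, None, None, None
    crit = dof * (np.log(2.0 * np.pi) + 1.0 + np.log(sigma2)) + logdet + logdet_xtx
    return crit, beta, XtX, sigma2


def reml_loglik(frame: ModelFrame, sigma_b2: float, sigma2: float, rho: float) -> float:
    """Restricted log-likelihood at given variance components (for checks)."""
    groups = _grouped_data(frame.y, frame.X, frame.pids, frame.days)
    n, p = len(frame.y), frame.X.shape[1]
    gamma = sigma_b2 / sigma2
    crit, beta, XtX, sig2_prof = _profiled_reml(gamma, rho, groups, n, p)
    # re-express at the *given* sigma2 rather than the profiled one
    if not np.isfinite(crit):
        return -np.inf
    rss = sig2_prof * (n - p)
    logdet = crit - (n - p) * (np.log(2 * np.pi) + 1.0 + np.log(sig2_prof))
    crit_at = (
        (n - p) * np.log(2 * np.pi)
        + (n - p) * np.log(sigma2)
        + logdet
        + rss / sigma2
    )
    return -0.5 * crit_at


def _check_full_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [terms[i] for i in piv[rank:]]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def fit_lmm_ar1(
    frame: ModelFrame,
    fix_gamma: float | None = None,
    fix_rho: float | None = None,
    n_starts: int = 3,
) -> FitResult:
    """REML fit of the random-intercept + AR(1)-residual model.

    ``fix_gamma`` (= sigma_b^2 / sigma^2) and/or ``fix_rho`` pin variance
    parameters instead of estimating them — with both fixed at zero the model
    collapses exactly to ordinary least squares.  Non-convergence is flagged
    on the result, not raised.
    """
    if frame.data.empty:
        raise ValueError("empty model frame")
    if frame.n_participants < 2:
        raise ValueError("need at least 2 participants")
    y, X = frame.y, frame.X
    _check_full_rank(X, frame.terms)
    n, p = len(y), X.shape[1]
    groups = _grouped_data(y, X, frame.pids, frame.days)

    free: list[str] = []
    if fix_gamma is None:
        free.append("gamma")
    if fix_rho is None:
        free.append("rho")

    def unpack(theta: np.ndarray) -> tuple[float, float]:
        it = iter(theta)
        gamma = np.exp(next(it)) if fix_gamma is None else float(fix_gamma)
        rho = np.tanh(next(it)) if fix_rho is None else float(fix_rho)
        return gamma, rho

    converged = True
    if free:
        def objective(theta: np.ndarray) -> float:
            gamma, rho = unpack(theta)
            crit, *_ = _profiled_reml(gamma, rho, groups, n, p)
            return crit if np.isfinite(crit) else 1e12

        bounds = []
        base = []
        if fix_gamma is None:
            bounds.append((-12.0, 8.0))
            base.append(np.log(0.5))
        if fix_rho is None:
            bounds.append((np.arctanh(-0.999), np.arctanh(0.999)))
            base.append(np.arctanh(0.2))
        rng = np.random.default_rng(20170515)  # fixed jitter stream for starts
        starts = [np.asarray(base)]
        for _ in range(max(0, n_starts - 1)):
            starts.append(np.asarray(base) + rng.uniform(-1.5, 1.5, size=len(base)))
        best = None
        for s in starts:
            res = optimize.minimize(
                objective, s, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200},
            )
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success and np.isfinite(best.fun))
        gamma, rho = unpack(best.x)
    else:
        gamma, rho = float(fix_gamma), float(fix_rho)

    crit, beta, XtX, sigma2 = _profiled_reml(gamma, rho, groups, n, p)
    if beta is None:
        raise ValueError("REML criterion not evaluable at the optimum")
    cov = sigma2 * sla.inv(XtX)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        beta=pd.Series(beta, index=frame.terms),
        se=pd.Series(se, index=frame.terms),
        sigma_b2=gamma * sigma2,
        sigma2=sigma2,
        rho=rho,
        loglik=-0.5 * crit,
        n_obs=n,
        n_participants=frame.n_participants,
        converged=converged,
        outcome=frame.outcome,
    )


# ---------------------------------------------------------------------------
# study model grid
# ---------------------------------------------------------------------------

#: display scale per outcome: entropy coefficients are reported x 10^-2
OUTCOME_SCALE = {"resting_hr": 1.0, "sample_entropy": 100.0}

_EXPOSURE_SETS = [("symptom_score",), ("mood",), ("symptom_score", "mood")]


def _result_rows(model_id, spec, fit, scale):
    rows = []
    for term in fit.beta.index:
        exposure, lag = "", np.nan
        for e in spec.exposures:
            for l in spec.lags:
                if term == f"{e}_lag{l}":
                    exposure, lag = e, l
        rows.append(
            {
                "model_id": model_id,
                "outcome": spec.outcome,
                "exposure_set": "+".join(spec.exposures),
                "exposure": exposure,
                "lag": lag,
                "term": term,
                "estimate": fit.beta[term] * scale,
                "se": fit.se[term] * scale,
                "ci_low": (fit.beta[term] - Z_95 * fit.se[term]) * scale,
                "ci_high": (fit.beta[term] + Z_95 * fit.se[term]) * scale,
                "scale": scale,
                "converged": fit.converged,
                "n_obs": fit.n_obs,
            }
        )
    return rows


def run_study_models(
    panel: pd.DataFrame,
    exposure_source: pd.DataFrame | None = None,
    outcomes: Sequence[str] = OUTCOMES,
    lags: tuple[int, ...] = (0, 1, 2),
    include_single_lag: bool = True,
    posthoc: bool = True,
    adjust: tuple[str, ...] = ADJUSTMENT_COVARIATES,
) -> pd.DataFrame:
    """The full study grid of fits, as a tidy results table.

    Per outcome: single-exposure (symptoms; mood) and multi-exposure
    distributed-lag models, plus single-lag sensitivity fits.  When a
    distributed-lag fit finds any symptom-score lag whose 95% CI excludes
    zero, an 11-model per-symptom post-hoc grid is fitted for that outcome.
    Entropy coefficients are reported on the x10^-2 scale (``scale`` column).
    """
    all_rows: list[dict] = []
    posthoc_outcomes: set[str] = set()
    for outcome in outcomes:
        scale = OUTCOME_SCALE.get(outcome, 1.0)
        specs: list[tuple[str, ModelSpec]] = []
        for exposures in _EXPOSURE_SETS:
            kind = "single" if len(exposures) == 1 else "multi"
            specs.append(
                (f"{outcome}~{'+'.join(exposures)}|dlag", ModelSpec(outcome, exposures, lags, adjust))
            )
            if include_single_lag:
                for l in lags:
                    specs.append(
                        (
                            f"{outcome}~{'+'.join(exposures)}|lag{l}",
                            ModelSpec(outcome, exposures, (l,), adjust),
                        )
                    )
        for model_id, spec in specs:
            frame = make_model_frame(panel, spec, exposure_source)
            fit = fit_lmm_ar1(frame)
            all_rows.extend(_result_rows(model_id, spec, fit, scale))
            if (
                posthoc
                and model_id == f"{outcome}~symptom_score|dlag"
            ):
                for l in spec.lags:
                    term = f"symptom_score_lag{l}"
                    lo = fit.beta[term] - Z_95 * fit.se[term]
                    hi = fit.beta[term] + Z_95 * fit.se[term]
                    if lo > 0 or hi < 0:
                        posthoc_outcomes.add(outcome)
    if posthoc:
        source = exposure_source if exposure_source is not None else panel
        for outcome in sorted(posthoc_outcomes):
            scale = OUTCOME_SCALE.get(outcome, 1.0)
            for item in SYMPTOM_ITEMS:
                if item not in source.columns:
                    continue
                spec = ModelSpec(outcome, (item,), lags, adjust)
                frame = make_model_frame(panel, spec, exposure_source)
                fit = fit_lmm_ar1(frame)
                all_rows.extend(
                    _result_rows(f"{outcome}~{item}|posthoc", spec, fit, scale)
                )
    return pd.DataFrame(all_rows)


# ---------------------------------------------------------------------------
# a-priori sample size
# ---------------------------------------------------------------------------

def _f2_power(n: int, f2: float, alpha: float, n_tested: int) -> float:
    """Power of the noncentral-F test of an R^2 increase at N observations."""
    df2 = n - n_tested - 1
    if df2 < 1:
        return 0.0
    crit = stats.f.isf(alpha, n_tested, df2)
    return float(stats.ncf.sf(crit, n_tested, df2, f2 * n))


def required_sample_size(
    f2: float,
    alpha: float = 0.05,
    power: float = 0.90,
    n_tested: int = 1,
    n_max: int = 10_000_000,
) -> int:
    """Smallest N reaching target power for an F-test of R^2 increase.

    ``n_tested`` predictors are tested jointly; the noncentrality parameter
    is f^2 * N and the denominator degrees of freedom N - n_tested - 1.
    Power is monotone in N, so the minimum is found by doubling then
    bisection.
    """
    if f2 <= 0:
        raise ValueError("f2 must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    lo = n_tested + 2
    hi = lo
    while _f2_power(hi, f2, alpha, n_tested) < power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power unreachable below N = {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if _f2_power(mid, f2, alpha, n_tested) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo
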