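# Methods

This note documents the models and procedures implemented in `pulsepanel`,
the assumptions behind the synthetic-data generator, and the numerical
choices made where the underlying method descriptions leave freedom.

## Heart-rate preprocessing

Raw input is a 1 Hz daytime beats-per-minute series per participant-day,
with missing samples from device dropouts.  Internally a series lives on a
regular grid at its nominal rate with `NaN` marking gaps, so gap length is
a run length.  Three sequential steps:

1. **Gap interpolation.**  A maximal missing run strictly shorter than
   20 s is replaced by linear interpolation between its flanking samples;
   runs of 20 s or longer, and runs touching the series edges, stay
   missing.  "Shorter than 20 s" is read strictly: a 19 s run is filled, a
   20 s run is not.  Observed values are never altered.
2. **LOWESS smoothing** with a 60 s bandwidth.  The smoother is spelled
   out as a tricube-weighted local *linear* fit over all samples within
   ±30 s of the target timestamp, zero robustness iterations — the
   deterministic Cleveland formulation.  Smoothing is applied
   independently within each contiguous gap-free segment, so long gaps are
   never bridged; segments of fewer than 3 samples pass through unsmoothed
   (counted in the preprocessing log).  On a regular grid the interior
   points reduce to a fixed-kernel weighted mean (the slope term vanishes
   by symmetry) computed by convolution; edge points get explicit weighted
   fits.  Fitted values are clamped to the physiological range
   [25, 250] bpm.
3. **Downsampling** to 0.1 Hz by centered means over consecutive,
   half-open 10 s bins anchored at the day's first sample (data-relative,
   not midnight-relative).  A bin with no observed sample yields a missing
   output sample, so the 0.1 Hz grid stays regular.  Six hours of fully
   observed 1 Hz data produce exactly 2160 output samples.

The test suite cross-checks the whole chain against an independently
coded, unoptimized reference implementation (per-point least-squares
fits, explicit scans) to 1e-9 bpm.

## Daily biomarkers

**Resting heart rate** is the minimum over the day of the 5-minute
rolling mean of the 0.1 Hz series.  Windows are 30 consecutive bins and
must be fully observed; sparse windows would otherwise produce
artificially low means.  No complete window → the day's value is missing
(logged, not an exception).

**Sample entropy** follows Richman & Moorman: with templates of length m,
B counts ordered template pairs (i<j, self-matches excluded) whose
Chebyshev distance is at most r, A the analogous count at length m+1, and
SampEn = −ln(A/B).  Both counts run over the same N−m template start
positions (the Richman–Moorman convention; some implementations use
N−m+1 starts for the length-m count).  Defaults: m = 2, r = 0.15 × the
participant's heart-rate SD.  Choices fixed here:

* The tolerance SD is the population SD (divisor N) over *all* of a
  participant's non-missing 0.1 Hz samples across the study period —
  computed on the preprocessed series, i.e. the same scale the entropy
  consumes.  A zero SD (constant record) is an error with guidance.
* Only the first 6 h of each day's data enter — read as the first 2160
  non-missing 0.1 Hz samples in time order, so every computed entropy
  uses an identical series length; days with fewer samples get a missing
  value.  Entropy is therefore present exactly for days passing the
  ≥2160-sample validity rule.
* A or B equal to zero means the entropy is undefined; it is coded
  missing rather than ±∞ to keep the modelling frame numeric.

The implementation (shifted distance-matrix ANDs) is tested to 1e-12
against a brute-force template-matrix oracle over randomized sweeps of N,
m and r.  Entropy is non-increasing in r throughout the tolerance range
the estimator is used in (r ≥ 0.125·SD in the property test); this is an
empirical regularity, not a theorem — in the sparse-match regime (very
small r) the ratio A/B can jitter non-monotonically.

**MVPA minutes**: time above the 40% heart-rate-reserve threshold,
resting + (max − resting) × 0.40, counting non-missing 0.1 Hz samples
strictly above threshold at 10 s each.  Maximal heart rate defaults to
the age-predicted 220 − age; the participant's observed maximum is a
configurable alternative, since the heart-rate-reserve method itself does
not pin the choice.

**Outlier filter**: within each participant, daily resting-HR and
entropy values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (quartiles by linear
interpolation of order statistics) are flagged and excluded from
modelling.  Fewer than 4 values → no filtering.

## Diaries and cohort filters

Eleven symptom items rated 0–4 sum to the daily symptom score (0–44); a
missing item makes the score missing.  Mood is a single 0–4 rating.
Medication "information available" means the three class flags
(antihistamine, corticosteroid, decongestant) are explicitly reported —
an all-zero report ("nothing taken") is complete, a blank one is not.
A *valid day* has ≥ 2160 0.1 Hz samples (≥6 h) and a complete diary;
participants with fewer than 10 valid days are excluded, and the filters
emit a flow report (participants/days in, out, per-rule exclusions).

## The distributed-lag mixed model

For participant i on calendar day d:

    y_id = x_id' beta + b_i + eps_id
    b_i ~ N(0, sigma_b^2)
    Var(eps_id) = sigma^2,  Corr(eps_id, eps_id') = rho^{|d-d'|}

`x_id` contains the exposure (symptom score and/or mood, both continuous)
at lags 0, 1, 2 — lag ℓ meaning the value reported on calendar day d−ℓ,
so a skipped diary day breaks the lag regardless of row order — plus the
adjustment set: age, sex, additional grass/dust-mite allergy, MVPA
minutes, NO₂, PM₁₀, the three daily medication flags, month one-hot
dummies (reference = first study month), a weekend flag, and the three
pollen-season flags.  Rows missing any required cell are dropped and
counted.  Adjustment columns that are constant or aliased in a given
frame (e.g. a medication class nobody took in a small cohort) are pruned
before estimation, R-style; the intercept and exposure terms are never
pruned.

**AR(1) over calendar days.**  The residual correlation exponent is the
calendar-day distance, so a gap of Δ days carries correlation ρ^Δ.
Observation-order AR(1) would overstate the correlation across missing
days.

**Estimation** is REML.  Given (σ_b², σ², ρ) the fixed effects are the
GLS solution; σ² is profiled analytically, leaving a 2-parameter search
over (log γ, atanh ρ) with γ = σ_b²/σ² — an equivalent, better-
conditioned transform of (log variances, shifted-logit ρ).  The search
uses L-BFGS-B with numerical gradients from 3 starts (one canonical, two
jittered from a fixed internal seed), keeping the best optimum; fits are
therefore deterministic given the data.  Per-participant covariance
blocks are grouped by day-spacing pattern so balanced panels factor one
small matrix per evaluation.  Non-convergence flags the result rather
than raising.  Confidence intervals are Wald, β ± 1.96·se with
se² = σ̂² diag[(XᵀV̂⁻¹X)⁻¹].  With both variance parameters fixed at
zero the fit collapses exactly to OLS (tested against statsmodels); the
restricted likelihood is tested to 1e-6 against a dense single-matrix
evaluation of the REML criterion.

`run_study_models` fits the full grid — two outcomes × {single-,
multi-exposure} × {distributed-lag, single-lag sensitivity} — and, when
any symptom-score lag CI excludes zero for an outcome, an 11-model
per-symptom post-hoc grid consuming the raw item columns.  Entropy
coefficients are reported ×10⁻² in output tables (a `scale` column
records the factor); `FitResult` objects stay in natural units.

**Sample size.**  `required_sample_size` finds the smallest N for which
the noncentral-F test of an R² increase (numerator df = number of tested
predictors, denominator df = N − n_tested − 1, noncentrality f²·N)
reaches the target power; power is monotone in N so doubling + bisection
suffices.  With f² = 0.01, α = 0.05, power 0.90 and 3 tested predictors
this yields N = 1422 participant-days.  The exact routine behind the
published figure is not fully specified, so the number of tested
predictors is an explicit parameter and the published value is treated
as an upper bound.

## Synthetic cohorts

The study's raw data were never deposited, so the generator *defines* the
test conditions; its defaults are the study conditions where stated and
field-realistic choices elsewhere.

**Tier A** draws daily panels directly from the estimating model's
generative process.  Defaults: 72 participants × 35 analysis days (plus
2 lead-in diary days feeding the lags of the first analysis days);
injected effects β_symptom,lag1→restingHR = 0.08 bpm per point and
β_mood,lag0→entropy = 0.80×10⁻² per point, all other exposure-lag
coefficients zero; resting-HR variance components σ_b = 6 bpm,
σ = 2.5 bpm, ρ = 0.3 (between-participant SD from the study's descriptive
sex-specific means ± SD; residual SD and ρ chosen as plausible
day-to-day values); entropy scale σ_b = 0.09, σ = 0.05, ρ = 0.3.
Covariate effects (recorded in the `GroundTruth` sidecar) are fixed
plausible values; month effects are zero, so the fitted month dummies
keep the refit correctly specified.

* **Symptom process**: a latent stationary AR(1) (ρ = 0.6) log-intensity
  floored to an integer and clipped to 0–44 — zero-inflated (~1/3 zero
  days), median ≈ 1, upper quartile ≈ 5, mirroring the heavy skew of real
  allergy diaries.  Daily totals are allocated multinomially over the 11
  items (sneezing/runny-nose/fatigue-weighted, each capped at 4).
* **Mood process**: a latent AR(1) (ρ = 0.5) Gaussian cut at fixed
  quantiles into 0–4 with 60% mass at 3 (median 3, IQR 3–3).
* Diary entries go missing as a whole with probability 0.05; outcomes are
  generated from the *latent* exposures, so missingness is reporting, not
  absence.

**Tier B** additionally builds 1 Hz daytime traces per participant-day:
baseline (N(62, 6²) bpm between participants) + a circadian dip (3 bpm
cosine, trough 14:00 — always inside the daytime window, so the daily
minimum plateau is comparable across days) + Poisson activity bouts
(~4 per 12 h, 20–60 bpm, ~15 min, raised-cosine edges) + white sensor
noise (2 bpm), clipped to [25, 250].  The whole trace is shifted by
δ_id = Σ β·exposure lags + b_i + AR(1) residual, so the resting heart
rate *extracted by the pipeline* (min of 5-min rolling means) equals
baseline − dip + δ_id up to small extraction noise and carries the
injected association.  Daytime windows start 06:00–09:00 and last
10–16 h (calendar-date day boundaries); gaps arrive at 2/h (80% short
2–15 s — interpolation fodder — 20% long 30–600 s); 10% of days are
short recordings (2.5–5.5 h) that fail the 6 h validity rule; 10% of
participants get only 4–9 days to exercise the compliance filter.  The
mood→entropy effect is **not** injected at the signal level — there is
no accepted forward model from mood to heart-rate entropy — so entropy
effect recovery is tested at tier A only.  Consequently tier-B entropy
values reflect only the trace model (smoothed noise), and their absolute
level is not calibrated to real wrist-worn data; passing tier-B tests
demonstrates pipeline correctness, not realism of the entropy scale.

Randomness: every draw descends from one root seed through
per-participant and per-day `SeedSequence` substreams, so identical
config+seed reproduces outputs bit for bit and adding participants never
perturbs existing ones.

What the generator does *not* emulate: beat-to-beat (RR) physiology and
conventional HRV structure, pollen-count or air-pollution fields
(exposures are participant-level constants), device-specific artifact
patterns, or adherence that correlates with symptom severity.  Passing
recovery tests therefore shows the estimator and pipeline are correct
under the assumed data-generating process, not that the process matches
any particular device.

## Problem sizes used in the test suite

Oracle equivalences run at full fidelity (100 entropy series up to
N = 300; 50 preprocessing days of 10–25 min each).  Parameter-recovery
and type-I-error checks use 200 replicates of the default 72 × 35 tier-A
panel; the end-to-end signal-level check uses one 20-participant ×
25-day cohort with full-length (10–16 h) 1 Hz days — sizes chosen to
make the Monte-Carlo error small relative to the tested tolerances while
keeping the suite runnable on a laptop.

## Known limitations

* The AR(1)-in-calendar-days residual model treats within-day ordering
  as exchangeable; sub-daily dynamics enter only through the biomarkers.
* Wald CIs rely on asymptotic normality of the GLS estimator; with very
  few participants the random-intercept variance is weakly identified.
* The entropy tolerance r is participant-specific but constant over
  time; drifting measurement scales would bias day-to-day entropy
  contrasts.
* `required_sample_size` reproduces a fixed-design F-test power
  computation; it is not a power analysis for the mixed model itself.
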