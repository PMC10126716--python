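# pulsepanel

Analysis pipeline for intensive-longitudinal wearable telemonitoring of
adults with allergic rhinitis: does day-to-day allergy burden (symptoms,
mood) move day-to-day autonomic balance, proxied by two heart-rate
characteristics — daily **resting heart rate** and daily **heart-rate
sample entropy**?

The package is aimed at biostatisticians and physiologists working with
1 Hz optical-wristband heart-rate data coupled to daily symptom diaries.
It provides every stage as a tested, reusable library (plus a thin CLI):

1. **Preprocessing** (`pulsepanel.preprocess`) — raw 1 Hz daytime series →
   linear interpolation of gaps shorter than 20 s → LOWESS smoothing
   (tricube local linear fit, 60 s bandwidth) → centered 10 s means
   (0.1 Hz).
2. **Daily biomarkers** (`pulsepanel.biomarkers`) — resting HR as the
   minimum of a 5-min rolling mean; sample entropy SampEn(m=2,
   r=0.15·SD_participant) over the first 6 h (2160 samples) of each day;
   MVPA minutes above 40% heart-rate reserve; within-participant Tukey
   (1.5·IQR) outlier removal.
3. **Diary scoring** (`pulsepanel.diary`) — 11 symptom items (0–4 each)
   summed to a 0–44 daily score, mood 0–4, medication-class flags;
   valid-day rule (≥6 h of HR data + complete diary) and the ≥10-valid-day
   compliance filter.
4. **Modelling** (`pulsepanel.model`) — distributed-lag (lags 0/1/2)
   linear mixed models with participant random intercepts and AR(1)
   residual correlation over calendar days, estimated by REML:

   y<sub>id</sub> = x<sub>id</sub>ᵀβ + b<sub>i</sub> + ε<sub>id</sub>,  b<sub>i</sub> ~ N(0, σ<sub>b</sub>²),  Corr(ε<sub>id</sub>, ε<sub>id'</sub>) = ρ<sup>|d−d'|</sup>

   with Wald 95% CIs, the full single-/multi-exposure ×
   distributed-/single-lag study grid, per-symptom post-hoc models, and
   the a-priori noncentral-F sample-size computation.
5. **Synthetic cohorts** (`pulsepanel.simulate`) — because the original
   study data are not deposited, a two-tier generator with *known,
   injectable effect sizes* stands in: tier A draws panels directly from
   the generative mixed model; tier B emits full 1 Hz traces + diaries
   whose quiet-floor level carries the injected lagged symptom effect, so
   the whole pipeline can be validated end to end.

## Worked example

Generate a 72-participant, 35-day tier-A cohort with a planted next-day
symptom effect of +0.08 bpm per symptom point and refit it:

```python
import pulsepanel as pp

cfg = pp.SimulationConfig(n_participants=72, days_per_participant=35, seed=1)
panel, truth = pp.generate_panel(cfg)
spec = pp.ModelSpec("resting_hr", ("symptom_score",))
fit = pp.fit_lmm_ar1(pp.make_model_frame(panel, spec))
print(fit.summary().loc[["symptom_score_lag0", "symptom_score_lag1",
                         "symptom_score_lag2"]].round(4))
print(f"rho = {fit.rho:.3f}   sigma_b^2 = {fit.sigma_b2:.2f}   sigma^2 = {fit.sigma2:.2f}")
```

prints

```
                    estimate      se  ci_low  ci_high
symptom_score_lag0    0.0076  0.0059 -0.0041   0.0192
symptom_score_lag1    0.0809  0.0059  0.0694   0.0925
symptom_score_lag2    0.0079  0.0058 -0.0035   0.0193
rho = 0.303   sigma_b^2 = 33.80   sigma^2 = 6.27
```

The planted lag-1 coefficient (0.08 bpm) is recovered with a CI excluding
zero, the two null lags are near zero, and the variance components match
the generating values (σ_b = 6 bpm, σ = 2.5 bpm, ρ = 0.3).  The same
round trip works at the signal level (`generate_signal_cohort` →
`preprocess_day` → `compute_daily_biomarkers` → `build_design` →
`fit_lmm_ar1`), which is how the end-to-end acceptance test validates the
pipeline.

The sample-size helper reproduces the usual a-priori computation:

```python
pp.required_sample_size(f2=0.01, alpha=0.05, power=0.90, n_tested=3)  # -> 1422
```

## Command line

```bash
pulsepanel simulate --seed 1 --out cohort/ --tier b   # full synthetic cohort
pulsepanel run-all  --seed 1 --out run/               # simulate → fit → report
pulsepanel sample-size --f2 0.01 --power 0.90 --n-tested 3
```

Exit codes: 0 success, 1 validation error, 2 finished with convergence
warnings.  `run-all` writes biomarker and results CSVs, a flow report of
the validity/compliance filters, and a manifest (config hash, seed,
version) so identical configs reproduce identical bytes.

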