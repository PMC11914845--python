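# Methods notes

This note records the modelling assumptions, default parameters, and
numerical choices behind `pdhf`, and what the synthetic-data tests do and
do not demonstrate about real monitoring data.

## The synthetic cohort generator

`pdhf.cohort.generate_cohort` emulates a home peritoneal-dialysis
telemonitoring cohort.  Within-patient dynamics for each monitored vital
are *patient intercept + small linear drift + i.i.d. Gaussian noise*:

- intercepts `N(mean, between_sd²)` per patient, daily noise
  `N(0, within_sd²)`; defaults (mean, between-SD, within-SD): weight
  (60 kg, 10, 0.5), urine (800 mL/d, 350, 150), SBP (135 mmHg, 15, 8),
  DBP (85 mmHg, 10, 5);
- drift slopes `N(0, slope_sd²)` with slope SDs of 0.005 kg/d, 0.5 mL/d,
  0.02 mmHg/d — slow personal trends over months;
- SBP/DBP intercepts correlated at 0.8 and daily noises at 0.5, so pulse
  pressure stays physiologic; a final clip enforces `sbp > dbp > 0` and
  `urine ≥ 0` on the rare residual violations;
- cohort marginals follow the published population this package models:
  6,635 patients, HF prevalence 0.71%, 61.15% female, ages and PD
  durations log-normal matched to the printed medians/IQRs (46.9 y with
  IQR 44.68–50.59; 1.0 y with IQR 0.53–1.64);
- follow-up uniform on 90–365 days; HF hospitalization lands uniformly
  in the last third of follow-up so a complete 15-day progression window
  always exists, and cases stop uploading on the hospitalization day;
- the planted HF signal is a mean shift, in within-patient SD units,
  applied only inside the progression window: weight +1, urine −1,
  SBP +1.5, DBP +2.  Diastolic pressure is deliberately the strongest
  channel, mirroring the predictor the analysis is expected to retain.

The linear-trend-plus-noise form matches the detector's assumed model on
purpose: it lets tests plant exact violations and verify calibration.
Real data depart from it in ways the generator does not emulate —
measurement dropout and irregular cadence (a `missing_rate` parameter
exists but defaults to 0 because no empirical rate is available),
device/user error outliers, autocorrelated physiology, seasonal effects,
and demographic dependence of HF risk.  In particular, HF assignment is
independent of sex and age here (the cohort config has no demographic
risk parameters), so full-pipeline AUCs on synthetic cohorts reflect the
vitals signal only and sit below what a cohort with strong sex/age
effects would show.  Passing tests demonstrate the *machinery* is
correct and calibrated, not that any particular real-world AUC will be
achieved.

For model-scale experiments that do need demographic effects,
`simulate_analysis_rows` skips the daily-stream layer and draws
patient-level rows directly from a logistic model, with default log-odds
set to the planted magnitudes (female OR 0.06, age OR 1.19 per year,
abnormal-DBP OR 38.79) and the model intercept calibrated by root
finding to a target prevalence.

## The personalized band

`fit_baseline` fits ordinary least squares of a vital against days since
the patient's first record (degree 1 by default; the polynomial degree
is configurable).  The band is the pointwise **prediction interval for a
new observation** at level 1 − α.  A mean-response confidence band is
available (`band="confidence"`) but is not the default: it shrinks with
n and would flag far more than α of points even for data following the
model, destroying the interpretation of the α = .05/.01 criterion.

Numerical/semantic choices:

- *Strict* inequality defines a discrete point; boundary values are not
  flagged.  With zero residual variance the band collapses onto the line
  and nothing is flagged.
- Flags are computed with the point included in the fit (each patient's
  series is fit once).  This is slightly conservative: the in-fit
  per-point flag rate at n = 100 is ≈ 0.043 for α = .05 because the
  point's own leverage deflates its residual.  The
  `leave_one_out=True` option flags on externally studentized residuals,
  whose null distribution is exactly t with n − 3 degrees of freedom, and
  restores exact α calibration; the calibration acceptance check runs in
  this mode, while a unit test pins the default mode's conservative
  behavior.  Monte-Carlo standard errors for calibration are computed at
  the patient (cluster) level because points within a patient share one
  fitted band.
- `min_obs = 10` per variable: bands from shorter series are numerically
  unstable; patients below the floor default to *normal* and are logged.
- Assessment windows are half-open `[start, end)`: for HF cases
  `[hf_date − 15 d, hf_date)`, for controls the trailing 15 observed
  days, giving both groups equal exposure duration.
- A known limitation: a *sustained* shift occupying a large fraction of
  a short series (window ≳ 25% of follow-up) is partly absorbed into the
  patient's own fitted trend and inflates the residual SD, which can
  mask the shift entirely.  At the study regime (follow-up ≥ 90 days,
  15-day window) the planted-signal response is strongly monotone in the
  effect size; below ~60 days of follow-up it is not.  Single-day
  spikes are detected at any series length.

The cohort-scale path (`discretize_cohort`) vectorizes the closed-form
simple-linear-regression algebra across all patients and is verified
against the per-patient object API on small cohorts.

## Study construction

- Progression window boundary: closed at `hf_date − 15 d`, open at
  `hf_date` — exactly 15 calendar days.  Windows that would begin before
  the first record are truncated with a warning.
- Case-control sampling keeps every case and draws `ratio × n_cases`
  controls uniformly without replacement; re-running at ratios 4/6/10
  never alters the case rows.
- The 80/20 split is stratified by outcome with per-stratum
  `round(0.8·n)` training counts (on 329 rows: 264/65), deterministic
  given its seed.  Stratification guarantees both classes appear in
  validation, which simple random splitting does not at 47 cases.
- One α criterion per dataset build; the four models consume the 95% and
  99% builds *over the same sampled patients and the same split*, so AIC
  and paired AUC comparisons are like-for-like.

## Models and selection

- Maximum-likelihood logistic regression (statsmodels) with Wald SEs;
  adjusted odds ratios are `exp(β)` with Wald 95% CIs.  A
  likelihood-ratio-based workflow was considered and rejected to keep
  the reporting style (per-variable AOR + CI + p) self-consistent.
- Backward elimination removes the largest Wald p ≥ 0.05 and refits;
  exact ties break by the canonical candidate order (sex, age, PD
  duration, weight, urine, SBP, DBP, pulse pressure).  If everything is
  eliminated an intercept-only model is returned with a warning.
- Near-separation is expected at this scale (tens of cases, abnormal
  rates of a few percent).  Non-convergence, |β| > 25, or Wald SE > 500
  triggers a ridge fallback (L2 penalty 0.5 on slopes, intercept free);
  the fit is marked `separation=True` and its reported log-likelihood
  and AIC are the *unpenalized* values at the penalized estimate.
- Selection: lowest AIC wins; when the lowest-AIC model is not also the
  highest-training-AUC model, the paired DeLong test arbitrates and the
  lowest-AIC model is kept unless the AUC difference is significant.

## Evaluation

- AUC is the tie-corrected Mann–Whitney statistic; its variance and the
  paired two-model test use the DeLong structural components, with the
  CI clipped to [0, 1].
- The classification threshold defaults to the Youden-optimal cutoff on
  the *training* ROC (a fixed threshold such as 0.5 is available); the
  validation report carries the threshold used.
- Decision curves use the threshold grid 0.01–0.99 (step 0.01);
  thresholds 0 and 1 are excluded with a warning since the net-benefit
  weight p_t/(1 − p_t) degenerates.

## Problem sizes used in the checks

Calibration and stability checks run at deliberately chosen sizes:
band calibration on 1,000 null patients × 100 days; oracle equivalence on
100 random small instances per quantity; Wald coverage on 200 replicates
of n = 2,000; selection stability on 100 replicates of the full 6,635-row
cohort sampled at ratios 4/6/10.  The full-scale acceptance run simulates
the complete cohort (~1.5 M daily records) once per invocation.
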