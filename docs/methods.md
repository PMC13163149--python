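# Methods

This note documents the models, estimators and defaults behind `respvar`,
what the synthetic cohorts do and do not emulate, and the numerical choices
a maintainer would want spelled out.

## Signal model and conditioning

A supine subject's abdominal wall rises over the inspiratory time `Ti` and
falls over the expiratory time `Te`; an inertial sensor between the xiphoid
process and the navel sees this as a quasi-periodic tilt superimposed on
the static gravity projection of each axis, wideband sensor noise, and slow
baseline drift.  Conditioning runs in four steps, each appended to the
signal's provenance record:

1. **Axis selection.** The axis with the largest Welch-spectrum power in
   the respiratory band (default 0.1–0.7 Hz, i.e. 6–42 breaths/min supine)
   is retained, mean-removed.  Ties break to the lowest axis index.
2. **Drift correction.** A centred rolling-median baseline (default 20 s)
   is subtracted.  A median was chosen over polynomial detrending because
   it is robust to apnoeic stretches.
3. **Zero-phase Butterworth bandpass** (forward–backward `sosfiltfilt`,
   default order 4).  Two bands play different roles: the *rate band*
   (0.1–0.7 Hz) drives axis selection and SNR estimation, but the waveform
   that breath timing is read from is filtered at a wider *waveform band*
   (0.05–1.5 Hz).  An asymmetric breath (`Ti ≠ Te`) carries its asymmetry
   in harmonics of the breathing frequency; clipping them at 0.7 Hz was
   measured to bias peak/trough times by ≈0.2 s, which is material when Ti
   itself is ≈1.7 s.  Zero-phase application matters for the same reason: a
   causal filter would shift every event time.
4. **Centred moving average** (default 0.5 s) with shrunken edge windows;
   no padding values are invented.

### Quality control

Per 5-s window, the peak-to-peak amplitude is compared with the recording's
amplitude scale, defined as the 90th percentile of window peak-to-peak
amplitudes.  A whole-signal IQR is *not* used as the scale: on a recording
that is mostly apnoeic the IQR collapses toward zero and the rule would
miss exactly the pattern it must catch.  Defaults (config-exposed):
windows below 25 % of the scale count as apnoeic; `apnea_fraction > 0.2`
flags the recording, and if breathing additionally resumes in clusters
(≥ 2 separate breathing runs between apnoeic runs) the `biot_pattern` flag
is set, mirroring the clinical exclusion of Biot's respiration.  Other
flags: `too_short` below 300 s (duration counted as whole samples, n/fs)
and `low_snr` below 3 dB in-band/out-of-band power ratio.  A flagged
recording is excluded from all downstream stages with a logged reason.

## Breath segmentation and timing refinement

A breath is a trough→peak→trough excursion; inspiration is the rising limb.
Extrema need prominence ≥ 0.3 × signal IQR and same-type separation
≥ 1.5 s (capping detectable rate at 40 breaths/min); strict alternation is
enforced by keeping the most extreme sample of any same-type run, and
partial boundary breaths are dropped rather than extrapolated.  Sensor
polarity is auto-resolved by requiring the median rising limb to be the
shorter limb (Ti < Te in resting eupnoea), overridable in config.
Amplitude is the peak height above the mean of its flanking troughs — a
tidal-volume proxy in arbitrary units; no volume calibration is attempted.

Pointwise extrema of a smooth waveform sit in low-curvature regions where
sample noise displaces them, so `refine_breaths` optionally re-estimates
each breath's (onset, peak, offset, amplitude) by local least squares
against a raised-cosine rise/fall template over the breath *and its
flanking half-breaths*, on a shape-preserving signal (drift-corrected but
not bandpassed).  Shared troughs of contiguous breaths are averaged; any
fit violating onset < peak < offset falls back to the detected times.

**Accuracy bound.** At 10 Hz sampling and a 10 dB dominant-axis power SNR,
the joint Cramér–Rao bound for per-breath Ti under this waveform model is
≈ 0.125 s (computed numerically for a contiguous train with shared
troughs), so *no* estimator can place more than ≈ 89 % of breaths within
0.2 s of truth under those conditions; the refinement reaches ≈ 82 %.  On
noiseless renderings, recovered event times match ground truth to within
one sample and refined times to a few hundredths of a second.  This bound
is worth keeping in mind when interpreting per-breath timing claims at low
sampling rates.

## RV metrics

For each parameter series (rate, Ti, Te, I/E ratio, amplitude) over a
300-s window (≥ 10 breaths required): sample-SD (n−1), CV = SD/mean,
RMSSD (mean over n−1 squared successive differences), triangular index
(series length / modal histogram count, bins anchored at 0), and Poincaré
SD1/SD2 using the *population* (n) variance so that SD1 = RMSSD/√2 holds
exactly on zero-mean-difference series; ellipse area = π·SD1·SD2.  Default
triangular-index bin widths: 0.1 s for Ti/Te, 1 breath/min for rate, 0.05
for I/E ratio, and IQR/10 for amplitude (whose units are arbitrary); the
heart-rate-variability convention of 1/128 s does not transfer to breath
series.  A constant series has triangular index 1 by definition.  Note the
triangular index is intrinsically discrete — with ~75 breaths a sub-bin
shift of a few values moves the modal count by 1 and the index by ≥ 6 % —
so exact-agreement expectations are phrased in modal counts, not relative
error.  "Respiratory-rate area" is implemented as the Poincaré ellipse
area of the rate series, the only area-like quantity in the metric set.

## Group comparison

Per metric, on the pooled cohort (patients + controls, complete cases,
dropped rows logged):

- **GAM residualisation** `metric ~ s(age) + sex + temperature +
  heart_rate + pulse_pressure`, Gaussian identity link, B-spline smooth of
  age with basis dimension 5, smoothing penalty chosen per metric by GCV
  `n·RSS/(n−edf)²` over a log-spaced grid (10⁻³…10⁴, 6 points).  The group
  label is deliberately excluded so the adjustment cannot absorb a genuine
  group effect; the adjusted value is residual + pooled mean, keeping the
  metric's scale.  Constant metrics pass through untouched.
- **Shapiro–Wilk** per group, report-only: inference is fixed to the
  Mann–Whitney U test regardless, since RV metrics are typically
  non-normal.
- **Bootstrap** (default B = 1000): subjects resampled with replacement
  within each group; statistic = difference of group medians (medians, not
  means, because the metrics are skewed); CI = 2.5/97.5 percentiles.
- **Mann–Whitney U**, two-sided; exact null distribution when
  min(n₁,n₂) ≤ 8 with no ties, tie-corrected normal approximation
  otherwise.  The U test supplies the primary p-value and the bootstrap the
  effect-size CI — the two are reported side by side rather than nested,
  and both operate on the adjusted metrics (adjust-then-resample order).
- **Benjamini–Hochberg** q-values across the 35-metric panel;
  significance at q < 0.05.

Calibration properties verified by simulation: with no group difference,
the mean FDR discovery fraction over 200 replicate 44+44 cohorts stays
below 0.07; a one-between-subject-SD elevation of the patient group's
I/E-ratio SD2 is detected at q < 0.05 in well over 80 % of cohorts.

## Prediction

Patients only, 35 RV features, standardisation inside each sklearn
pipeline so it is fitted on training folds only (verified by scaler-state
and canary-feature tests).

- **CRS-R regression** (random forest, elastic net, SVM-RFE, PLS): nested
  CV — outer 5-fold for metric estimation, inner k-fold random search
  (default 5-fold, 50 draws) for tuning; MSE/RMSE/MAE/R² from pooled
  outer-fold predictions; a final tuned fit on all data provides the
  deployable model and permutation-importance top-20 (ties broken by
  feature name).  SVM-RFE ranks features with a linear-kernel SVR inside
  RFE and predicts with an RBF SVR, per standard practice.
- **Outcome classification**: stratified 70/30 split; within the training
  partition, selection and tuning by LOOCV + random search (configurable
  to k-fold for speed).  Pipelines: direct RF; elastic-net-penalised
  logistic whose non-zero coefficients select features for a plain
  logistic fit; RF permutation-importance top-k (k tuned) into logistic.
  Validation metrics at a 0.5 threshold plus the full ROC so users who
  weigh sensitivity more heavily can re-threshold.
- Search spaces and budgets all live in the config; `predict_single`
  scores one subject from a saved, versioned model bundle.

Covariates are not fed to the predictive models by default (RV-only
features); a config flag could add them, and this choice is recorded here
because the alternative is equally defensible.

## Synthetic cohorts

The generator defines the study conditions for every test:

- **Breath process**: Ti, Te and amplitude follow independent stationary
  Gaussian AR(1) series (`value = mean + sd·z`, z unit-variance with lag-1
  autocorrelation ρ), floored at 0.3 s (times) to stay physiological —
  the simplest process with separately tunable mean, SD and
  breath-to-breath memory.  Controls: Ti 1.7 s, Te 2.3 s (15 breaths/min),
  sd 0.15/0.20 s, ρ = 0.3.  Patients: Ti 1.5 s, Te 2.0 s, sd 0.25/0.35 s,
  ρ = 0.5 — more variable, more autocorrelated breathing whose net effect
  is an elevated I/E-ratio SD2 in patients, the direction the group
  comparison is designed to detect.
- **Rendering**: each breath is a raised-cosine rise over Ti and fall over
  Te scaled by its amplitude, projected on the three axes by a fixed unit
  orientation vector (z-dominant), plus per-axis gravity offset, white
  noise and linear drift; 10 Hz sampling, 330-s recordings so a full 300-s
  analysis window survives boundary losses.
- **Covariates** are drawn from per-group normals matching the reported
  cohort's baseline table (patients: age 55.8 ± 17.8 y, HR 83.6 ± 16,
  T 36.6 ± 0.4 °C, PPD 46.5 ± 13 mmHg, 13/44 male; controls: 45.8 ± 17,
  71.6 ± 11.7, 36.4 ± 0.2, 45.4 ± 9.8, 22/44 male).  Confounding is real,
  not cosmetic: heart rate scales breathing rate (+0.4 %/bpm above 75),
  timing SDs grow quadratically away from mid-life age, and amplitude SD
  grows with pulse pressure — structure the GAM stage must remove.
- **Clinical links**: CRS-R = clamp(round(14 − 25·ie_ratio_sd2 −
  15·rate_cv + ε), 0, 23) with ε ~ N(0, 3) score units; improvement is
  Bernoulli with log-odds 1.8 − 8·ie_ratio_sd2.  With zero noise the
  latent score is an exact linear function of the true features (the link
  calibration tests rely on this).  Controls carry no CRS-R or outcome.
- **Pathological patterns**: Biot's respiration alternates clusters of
  3–5 breaths with 10–30 s apnoeas (cluster parameters from the clinical
  description; used only to exercise QC); Cheyne–Stokes modulates
  amplitude on a 60-s cycle with apnoeas at the nadir; ataxic triples the
  SDs and inserts irregular 2–8 s pauses.

What the generator does **not** emulate: cardiac artifacts, sensor
quantisation or Bluetooth dropouts, posture changes, non-stationary
drift beyond a linear term, and any coupling between breath shape and
disease beyond the variability structure above.  Passing tests therefore
demonstrate that the pipeline recovers what it is pointed at under these
idealised conditions, not that it is robust to every artifact of bedside
recording.

## Problem sizes and reproducibility

Statistical properties are checked at the cohort size of interest
(44 + 44): type-I error over 200 replicate cohorts in the test suite
(80 in the acceptance script), power over 100 (60), model-ordering over
20 seeds (10), null AUC over 50 (20), breath recovery over 50 (30) — the
script's sizes are chosen so a full from-scratch run completes in about
ten minutes on one CPU, and every quantity derives from the single
`--seed` argument.  Replicate loops use the generator's truth tables
directly (no waveform rendering) because rendering and re-detecting
signals is covered by the dedicated recovery and QC checks; this keeps the
statistical replications about thirtyfold cheaper.  End-to-end runs are
byte-reproducible: rerunning the demo configuration with the same seed
yields identical feature, comparison and model-report files, and the run
manifest records the seed and a hash of the resolved config.

## Known limitations

- Per-breath timing at 10 Hz is information-limited (see the Cramér–Rao
  analysis above); claims finer than ~0.1 s per breath at realistic SNR
  should be treated with suspicion.
- The triangular index is unstable at 300-s windows (~75 breaths); its
  discreteness is documented rather than smoothed away.
- Amplitude is in arbitrary units throughout; only scale-free amplitude
  metrics (CV, triangular index with data-driven bins) are comparable
  across sensors without calibration.
- The outcome benchmark rests on a single stratified split at n = 44; its
  variance across seeds is large, which is why the package reports the
  ROC and the suite tests distributional properties over many seeds
  rather than any single split's numbers.
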