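# Methods

This note documents the models, the synthetic-data generative
assumptions, and the numerical choices behind the `fcnef` package.

## Session timing and segmentation

A neurofeedback session is a 150 s rest block followed by six trials of
14 s cue ("equals"), 42 s task ("plus": 40 s induction of which the
first 2 s are discarded for hemodynamic delay and the remaining 38 s
enter the FC computation, then 2 s calculation), and a feedback display.
The first 10 rest volumes are discarded for steady-state magnetization.

The per-trial feedback display duration is not a protocol constant
anywhere we could anchor it; the default (26/6 s) is the value that
makes a six-trial session total 512 s at TR = 1 s, and is documented as
an inference, not a measured value. It only affects how much of the
session tail is labelled; no computation reads the feedback window.

Seconds-to-volumes conversion floors (`floor(seconds / TR)`): a window
never includes a partial-period volume. All windows are half-open
`[start, stop)` with 0-based indices.

## Preprocessing

* **Framewise displacement** uses Power's formula:
  `FD[t] = Σ|Δtranslation| + R·Σ|Δrotation|` with head radius
  R = 50 mm and `FD[0] = 0`. Rotations are stored in radians
  (converted on read if a file declares degrees; SPM `rp_*.txt` column
  order — 3 translations then 3 rotations — is assumed).
* **Nuisance regression** always includes an intercept. The design is
  6 motion + global + CSF + grey-matter means, plus backward-difference
  derivatives of all of them (first element 0); "derivative" could also
  mean an analytic derivative of a fitted curve, but the backward
  difference is the convention real-time pipelines use and is exactly
  invertible. High-motion volumes enter as unit indicator columns in
  the online variant; the offline variant removes those frames instead
  (scrubbing). Regression and filtering are applied sequentially
  (regression first), matching the order in which the steps are
  described rather than a single combined model. Exact duplicate
  columns are dropped; a rank-deficient design falls back to a
  pseudo-inverse fit with a warning.
* **Band-pass filtering** is a second-order Butterworth applied
  forward-backward (`filtfilt`), i.e. zero-phase with a squared
  magnitude response. The filter family and bands are fixed by the
  protocol; the order is this package's choice — order 2 is the common
  choice for short BOLD segments because higher orders ring on 38-volume
  windows.
* **Spatial smoothing** is a per-volume 3D Gaussian with
  `sigma = FWHM / (2·sqrt(2·ln 2)) / voxel_size` per axis and
  reflective boundaries (sum preserved to well under 1%).

## Per-trial FC and the feedback score

The per-trial pipeline is: subtract each ROI's rest-period mean,
regress out the nuisance design, band-pass 0.008–0.3 Hz, Pearson over
the trial's 38-volume induction-use window.

The sham-day baseline is computed in Fisher z space: per-trial
z = atanh(r), mean z̄ and sample SD s (ddof = 1, requiring ≥ 2
distinct trials). The score map fixes three anchors — baseline → 50,
baseline − 1 SD → 100, baseline + 1 SD → 0, clamped beyond — and the
protocol states nothing between them. We interpolate **linearly in z**
(the space in which the baseline statistics live); the alternative
reading, an SD taken over raw correlations and applied in r space, is
available via `compute_baseline(..., anchor_space="r")`. Scores are
kept at floating precision; no rounding is applied.

Sham feedback draws raw values from Normal(50, 30.3); the displayed
score is clamped to [0, 100] but the raw draw is retained in
`ShamDraw.raw` so the generating parameters remain recoverable from
saved scores.

## Localizer

Condition regressors are block boxcars convolved with the canonical
double-gamma (Glover) HRF via nilearn's `compute_regressor`; motion
parameters are appended unconvolved. Conditions are modeled without
orthogonalization by default; a sequential-orthogonalization switch
(each column against its predecessors, in the modeled order) exists
because some packages orthogonalize and the order is otherwise
unspecified. The GLM is voxel-wise OLS with an always-appended
intercept; dof = t − rank.

Peak selection: one-sided t threshold with Bonferroni family-wise-error
control over in-mask voxels (the simplest defensible FWE rule;
random-field theory is out of scope), 18-neighbour connected
components, minimum cluster size 10 voxels, and ties broken to the
lowest linear voxel index in scan order. Sphere ROIs contain every
voxel whose center lies within 8 mm (Euclidean, through the affine) of
the peak, clipped at grid edges.

## Group analysis

Change scores are later-day minus Day-0 values, one record per
participant and horizon. The outlier rule excludes values more than
k = 2 sample SDs from the mean, computed once over all values in a
single pass (no iteration, candidate included in the statistics).

With one change score per participant there is no replicated grouping
factor, so the "mixed" change models reduce to ordinary linear models;
they are fit by maximum likelihood so that nested models can be
compared by likelihood-ratio test and AIC. AIC is computed as
2k − 2·logLik with k counting the residual variance as an estimated
parameter. Per-term F tests are drop-one-term (marginal) comparisons of
nested OLS fits. The leave-one-out analysis refits the base model
(Δsymptom ~ Δrs-FC) on n − 1 participants and predicts the held-out
change; the reported statistic is the Pearson correlation between
actual and predicted changes. Two-sided tests throughout; no
multiple-testing correction is applied.

The task-score-by-day model is a true mixed model (random intercept per
participant, fixed numeric day effect, ML fit via statsmodels MixedLM);
its "main effect of day" is the Wald test of the slope.

## Synthetic data: what it emulates, and what it does not

The latent ROI pair is a bivariate Gaussian AR(1) process: innovations
drawn with the target correlation (Cholesky of the 2×2 correlation
matrix) and filtered with a common AR coefficient (default 0.3), which
leaves the stationary cross-correlation equal to the innovation
correlation. Session generation varies the innovation correlation per
volume, so each trial's induction period carries its own planted value.
On top of the latent pair:

* shared global/CSF/grey-matter components (smooth AR(1), phi = 0.95)
  with amplitudes 1.0 / 0.5 / 0.8 relative to the unit-variance latent
  signal — these are exactly the regressors handed to the pipeline, so
  regression removes them;
* a shared linear drift of 1 SD per run. The pipeline has no drift
  regressor (the stated design does not include one), so a small
  residual of the drift survives regression and the 0.008 Hz high-pass,
  attenuating a planted resting correlation by roughly 0.01 at
  n = 590 — an honest property of the modeled conditions, retained
  deliberately;
* optional independent measurement noise (default 0: the AR innovations
  already play that role for correlation estimation);
* head motion as a small random walk (translation steps sd 0.005 mm,
  rotation steps sd 1e-4 rad), far below the 0.5 mm FD threshold, with
  requested spikes as permanent single-frame 1 mm translation steps so
  FD exceeds 0.5 mm at exactly the requested frames.

Localizer runs plant blobs whose amplitude follows a Gaussian spatial
profile (sigma = radius/2) times the condition regressor, on top of
unit Gaussian noise; the planted center is therefore the
strongest-responding voxel and "exact peak recovery at high SNR" is
well defined.

Cohorts plant `Δsymptom = intercept + β·Δrs-FC (+ experiment-2 shift)
+ N(0, residual_sd)`. Defaults mirror the study population: 19
participants split 9/10 across two experiments, Day-0 BDI ~
N(14.3, 5.1), Day-0 resting FC ~ N(0.01, 0.05), FC change ~
N(−0.07, 0.10), β = 20 BDI points per FC unit, residual SD 2,
no experiment effect. The brooding and RRS-depression factors track the
FC change with 0.4× and 0.5× the primary slope; reflection and trait
anxiety do not track it at all — mirroring the dissociation the
paradigm is designed to show. Follow-up (1- and 2-month) rows are
emitted for experiment-2 participants only.

**Not modeled:** physiological (cardiac/respiratory) noise, spatial
structure of the two ROI signals (the generators work at the
ROI-mean level except for localizer volumes), scanner drift
nonlinearity, session-to-session learning dynamics, and any real
spatial anatomy (masks are synthetic). Passing tests therefore show
that the estimators recover what the pipeline assumes — correlated
Gaussian signals plus the modeled confounds — not that they are robust
to everything real BOLD data contains.

## Problem sizes used by the test suite

Monte-Carlo checks use: 10⁴ samples for raw planted-correlation
recovery; 100 seeds × 590 volumes for resting-FC recovery; 100–204
simulated trials for per-trial FC recovery; 100 seeds of n = 200
cohorts for CI coverage; 1000 seeds of n = 200 cohorts for null
calibration (the χ²(2) reference for the likelihood-ratio statistic is
asymptotic, and at small n the ML LRT is visibly inflated — n = 200
puts the finite-sample deviation well inside the Kolmogorov–Smirnov
tolerance); 10⁶ draws for the sham-generator moments. Brute-force
oracle comparisons run on instances of a few hundred volumes or a few
thousand voxels.

## Known limitations

* The FWE rule is Bonferroni; with smoothed data it is conservative
  relative to random-field thresholds.
* The online pipeline filters the whole session before windowing each
  trial; the 0.008 Hz high-pass has a long impulse response, so a small
  amount of cross-trial leakage is inherent to the design.
* Pearson estimates over 38-volume windows are noticeably attenuated
  toward zero (≈ 0.03–0.04 at |r| = 0.5–0.6) by the band-pass and the
  short window; baselines and feedback inherit this, exactly as an
  online system would.
* `exclude_outliers` computes mean/SD with the candidate included; with
  tiny samples a gross outlier can inflate the SD enough to save
  itself.
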