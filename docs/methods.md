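# Methods

This note documents the statistical procedure, the choices made where
the design was genuinely open, and what the synthetic test bed does and
does not establish.

## Pipeline overview

1. **Session streams.** Each participant plays two games, *Rocket*
   (11 challenges) and *Connect* (6). Per challenge three raw streams
   are read: gaze direction samples (unit 3-vectors in camera
   coordinates, ~28 Hz), touch gestures (timestamped pixel polylines,
   ~100 Hz), and 7-class emotion probability frames. Timestamps are
   seconds from challenge start on a shared clock; whether the video and
   touch clocks of a real device are synchronised is a property of the
   acquisition system, and the pipeline assumes they are.
2. **Features.** 16 per challenge: 4 eye-tracking, 5 digit-tracking,
   7 emotion (see below).
3. **Binning.** Each feature series is averaged into 100 equal-width
   time bins over [0, duration], giving a 16 × 100 = 1600-column row per
   (participant, challenge), assembled per game.
4. **Constructs.** A PCA fitted on a reference cohort is applied,
   unchanged, to the analysis cohort; the first three component scores
   are the multimodal biometric constructs MBC1–MBC3. Per-modality
   matrices give unimodal constructs the same way.
5. **Association.** Each age/sex-adjusted measure is regressed on the
   three constructs with a random intercept per challenge (REML), with a
   Huber-robust fixed-indicator variant, Holm–Bonferroni correction, and
   Cohen's D effect sizes; participant characteristics are compared
   between sexes with t / Mann–Whitney / chi-squared tests.
6. **Modality comparison.** Per measure, the in-sample MAE of each
   unimodal construct model is expressed as percent change against the
   multimodal baseline.

## Feature definitions and conventions

- **Angular distance** α = arccos of the normalised dot product of
  consecutive gaze directions, in degrees, clamped to [0, 180]. Gaze
  vectors within 1e-3 of unit length are renormalised on read; anything
  further off is a hard error.
- **Angular velocity** = α/Δt per consecutive-sample interval; **total
  angular distance** is the running sum of |α|.
- **I-VT.** An interval with velocity strictly below the threshold
  (default 100°/s) is a fixation interval; a velocity *at or above* the
  threshold is a saccade (the fixation definition is "below", so ties go
  to saccade). Consecutive same-label intervals merge into events.
  Fixation events shorter than the minimum duration (default 70 ms) are
  relabelled *undefined* and dropped from the event list; they do not
  merge their flanking saccades, which stay distinct events. No velocity
  smoothing is applied before thresholding; a causal moving average is
  available downstream and off by default. Both the per-interval label
  series (saccade = 1, fixation = 0, undefined = missing) and the event
  summaries are emitted; the binning stage consumes the per-interval
  series.
- **Touch features.** Per gesture: mean of point-by-point speeds
  (zero-Δt duplicate samples are collapsed first, so division by zero is
  impossible), path length, duration, vertical extent max(y) − min(y)
  (invariant to the screen-origin convention), and area. The "minimal
  polygon" area is realised as the convex hull — the canonical minimal
  convex polygon containing the points — with a bounding-box alternate
  behind `area_method`; a gesture with fewer than 3 non-collinear points
  has area 0, and a single-point gesture is all-zero. Gesture series are
  indexed by gesture midpoint time.
- **Emotion.** The seven probabilities are inputs (from file or the
  generator), never computed from video. Optional simplex
  renormalisation (off by default, matching the weaker "between 0 and 1"
  input contract) rescales each frame to sum 1 and errors on zero-sum
  frames. Column order is fixed: anger, disgust, fear, happiness,
  neutral, sadness, surprise.

## Binning and missing data

Bins are half-open [lo, hi) with the final bin closed so t = duration is
kept. The bin value is the mean of the observations falling in it.
Empty interior bins are linearly interpolated between the nearest
non-empty bins; leading/trailing empty bins carry the nearest non-empty
value. A feature with no observation in a whole challenge (e.g. a
challenge without touches) is an all-missing 100-bin block, flagged in
the matrix mask. A participant missing a challenge contributes an
all-missing row (with a warning) so row indexing stays rectangular.

## Construct PCA and reference transfer

Missing cells are imputed by reference column mean; columns are
standardised to mean 0, sd 1 using the *reference* cohort's statistics
(standardisation before eigendecomposition is the default, exposed as a
switch); zero-variance columns are dropped and recorded in the model.
Eigenvectors come from a full SVD and are signed so each component's
largest-magnitude loading is positive, making the fit deterministic
across linear-algebra backends. Projection of any target cohort uses
the reference means, sds and eigenvectors only — target statistics never
enter, which the tests enforce by checking that subsetting or permuting
target rows leaves projections unchanged. Three components are retained
for the headline analysis.

Rows are (participant, challenge), not per-participant concatenations:
this is what lets the challenge act as the mixed model's random effect
while keeping the "n features × 100 bins" vectorisation per challenge.
The time-series "moving average" treatment is realised as causal
moving-average smoothing of each feature series (window 1 = off by
default); no MA(q) error model is estimated.

## Association models

- **z-adjustment**: z = (raw − normative mean)/normative sd for the
  participant's sex and age band; a missing normative cell is a hard
  error naming (measure, sex, age band).
- **Mixed model**: y ~ const + MBC1 + MBC2 + MBC3 with a random
  intercept per challenge, REML. Fixed-effect inference uses a t
  reference distribution with df = rows − fixed effects − challenge
  levels, a small-sample approximation in the spirit of residual-df
  corrections for mixed models; with 60 rows and 6 challenges the
  measured 95% CI coverage for a known coefficient is about 93–95%,
  against roughly 91–95% for the asymptotic normal. Optimisation falls
  back from L-BFGS to Powell, and a fit whose likelihood is degenerate
  (or whose Wald statistics are undefined) is reported as the boundary
  model — OLS with zero random-intercept variance — flagged `singular`,
  never raised. Residual normality (Shapiro–Wilk) and homoscedasticity
  (|residual| vs fitted Spearman) screens at α = 0.05 are attached as
  flags.
- **Robust model**: Huber M-estimation with challenges as fixed
  indicator terms, since robust mixed models are not standard; this is
  an approximation to the random-intercept specification and agrees
  with it on clean data.
- **Holm–Bonferroni** is implemented from the step-down definition
  (adjusted_(i) = max_{j≤i} min(1, (m−j+1) p_(j))) and cross-checked in
  tests against both a brute-force evaluation and the statsmodels
  implementation. The family is all (measure × component) tests within
  one game and model flavour — the widest defensible choice; undefined
  p-values from singular fits are excluded from the family with a
  warning.
- **Cohen's D** per component uses a median split of the component's
  scores, pooled-sd standardised.
- **Group comparison**: Shapiro–Wilk at α = 0.05 in both groups decides
  t vs Mann–Whitney; categoricals use chi-squared; degenerate groups are
  skipped with warnings.

## MAE modality comparison

One mixed model per (measure, modality set); predictions are fixed
effects plus estimated challenge effects; MAE is in-sample (fit and
evaluate on the same cohort), matching the comparison's purpose of
ranking model specifications rather than validating out of sample (a
cross-validated option is available but off by default). Percent change
= 100·(MAE_unimodal − MAE_multimodal)/MAE_multimodal, stored unrounded;
the report view rounds to integers and fixes the baseline column at 1.

## Synthetic-data generator

The generator produces cohorts with the structure the analysis assumes,
plus the ground truth to test against:

- **Gaze**: alternating fixations (exponential dwell, mean 0.4 s,
  floor 0.15 s, small cumulative jitter ≈ 1°/s apparent velocity) and
  ballistic saccades with a raised-cosine displacement profile
  (amplitude mean 10°, sd 1°, peak velocity 300°/s), sampled at 28 Hz.
  Sampling bounds detectability: whatever the underlying profile, a
  sample landing mid-saccade halves the point-to-point displacement, so
  only amplitudes above 2·threshold/rate (≈ 7.2° at 100°/s, 28 Hz) are
  guaranteed to cross the I-VT threshold. With deterministic amplitudes
  (`saccade_amplitude_sd = 0`) every generated saccade is detectable and
  the per-challenge saccade count is an exact oracle.
- **Touch**: 1 + Poisson gestures per challenge (rate 0.25/s), smoothed
  random-heading polylines at 100 Hz, speed ~600 px/s on a
  1920 × 1200 px screen.
- **Emotion**: iid Dirichlet frames at 28 Hz, neutral-dominated
  concentration tilted by a latent arousal factor.
- **Latent structure**: three per-participant factors (oculomotor,
  motor, arousal) ~ N(0, 1) drive the stream intensities; per-challenge
  N(0, 0.5) shifts add a true challenge effect to the streams. Raw
  assessment scores are normative mean + sd · (loadings·latents +
  N(0, 0.6)); default loadings tie working-memory measures to the
  oculomotor factor, processing-speed measures to the motor factor, and
  behavioural scores to arousal, with standardised effects 0.2–0.8.
- **Norms**: per measure, means increase linearly with age band
  (1–4 points/year) with a small sex offset; sds 4–10, positive in every
  cell; bands (7–9, 9–11, 11–13, 13–15 years).
- Cohort sizes default to the study conditions: 24 analysis
  participants, 63 reference participants.

Everything is deterministic under a seed (byte-identical output
directories) and every distributional choice above is a stand-in: the
generator reproduces the *statistical shape* the pipeline assumes
(stream rates, alternating gaze events, simplex emotions, linear
latent-score links, challenge effects), not children's actual behaviour.
Passing tests therefore establish correctness of the computations and
calibration of the inference under the assumed model — they do not
certify effect sizes or screening performance on real cohorts.

## Problem sizes used in tests and acceptance runs

The test suite simulates small cohorts (5–15 participants, 5–7 s
challenges) chosen so the full pipeline — including 11 + 6 challenges
per participant and all 1600 matrix columns — is exercised end to end;
the structural and contract properties checked are size-invariant.
Oracle equivalences run at 1,000 random gaze traces, 500 random point
sets and 1,000 random p-vectors; mixed-model recovery uses 60-row
designs with 100 coverage and 500 null simulations; the modality
comparison medians use 50 simulated targets.

## Known limitations

- I-VT at 28 Hz cannot detect small saccades (see the bound above), and
  event durations are quantised to the frame interval.
- The robust flavour conditions on challenges as fixed effects, so its
  coefficients are not exactly comparable to the mixed model's when the
  challenge variance is large.
- In-sample MAE favours larger modality sets; between-modality
  differences should be read as descriptive, not as generalisation
  error.
- With 6–11 challenge levels, random-intercept variance estimates are
  noisy and boundary (singular) fits are expected and reported rather
  than discarded.
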