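# Methods

This note records the modeling choices behind `rampload`: what each
stage assumes, the defaults and why, what the synthetic cohort does and
does not emulate, and the numerical conventions at the edges.

## Frame-level fatigue engine

The engine consumes one eye-openness observation per camera frame and
maintains a single pass of state:

- **EAR** uses the standard six-landmark aspect ratio. The deployed
  pipeline may instead supply precomputed EAR values; landmark
  detection is outside this package (an input adapter concern).
- **PERCLOS** is the fraction of closed frames (EAR strictly < 0.3) in
  a sliding window of the most recent 300 frames, recomputed every
  frame. During warm-up the partial window is used rather than
  emitting no value. Invalid (dropped) frames are excluded from both
  numerator and denominator, so the value is the closed fraction
  *among observed frames*; a window with no valid frame yields NaN,
  handled downstream as missing. At 30 frames/s the window spans 10 s.
- **M = 0.3·EAR + 0.7·PERCLOS** uses the per-frame EAR, not a smoothed
  one; the PERCLOS term already carries the smoothing.
- **Runs and levels.** A run counts consecutive frames with M
  strictly above 0.605. Boundary conventions: mild requires N > 5,
  severe and the alarm require N ≥ 50 (inclusive). An occurrence is
  attributed to the frame at which the run terminates — or the last
  frame, for a run still open at stream end — which is also how
  occurrences are assigned to minutes.
- **Dropped frames.** A run should not be fabricated or destroyed by
  detector dropouts at the ~6% rate seen in deployment. Up to four
  consecutive invalid frames carry the last M forward; a fifth closes
  the run. Runs terminate only when M falls to ≤ 0.605 (or the stream
  ends); alarm acknowledgment does not terminate a run.

## Unitization and missing data

Minutes average EAR/PERCLOS/M over their valid frames when less than
half the frames are missing. At ≥ 50% missing, each frame-derived
average is predicted by a random-forest regression (200 trees) trained
on the complete minutes, with the minute index and the sensor
indicators as predictors. The prediction is clamped to the column's
observed range — an automated plausibility check standing in for
manual review, chosen for reproducibility — and blended with the
minute's own valid-frame average, weighted by frame share. Fatigue
occurrence counts ignore missingness entirely: a run counts in the
minute where it terminates.

The indicator catalogue nominally has 20 entries; the area-of-interest
dwell percentage entry covers two screen regions (AOI0: the simulation
display, AOI1: the monitor display) and is stored as two columns,
giving 21 physical indicator columns. The catalogue carries two
distinct "average gaze duration" indicators (different tracker
exports); both are kept under disambiguated names
(`gaze_duration_avg`, `gaze_duration_avg_alt`) rather than silently
merged.

## Workload labeling

Clustering runs on the variance-prescreened indicators plus the minute
index (the time feature), z-scored, with subject identity one-hot
encoded and the dummies z-scored too. The per-minute alarm flag is
deliberately left out of the clustering features and joins the feature
pool only at the supervised stage: the clustering design targets the
fatigue / eye-movement / respiration indicator families, and a rare
binary flag would otherwise dominate the standardized geometry.

PCA reduces to two components (sign-fixed by orienting each
component's largest-magnitude loading positive, so projections are
reproducible). K-means (10 restarts, seeded) with silhouette selection
over K = 2..6 picks the cluster count; exact ties go to the smaller K.
Only the two-cluster outcome supports level assignment: the cluster
with the smaller median minute is labeled low, the other high, with
the mean minute breaking an exact median tie. A switch allows
clustering on the full standardized matrix instead of the 2-D
projection, and another drops the time feature, for sensitivity
analysis; the defaults are the 2-D projection with time included
(consistent with time later carrying large supervised importance).

## Feature weighting, screening, classification

- The variance prescreen drops indicators whose session
  coefficient of variation (sd/|mean|) falls below 0.05; fatigue
  metrics are exempt. The default separates the generator's stable
  channels (CV ≈ 1–3%) from its workload-sensitive ones (CV ≳ 8%) with
  a wide margin on either side.
- Random-forest importances (300 trees, impurity-based) are computed
  on a seeded 80% training split and normalized to sum 1. Subject
  one-hot dummies keep individual importances so screening judges each
  alone.
- Screening is inclusive (importance ≥ threshold) at both 0.010 and
  0.040 — the inclusive reading reproduces both published screening
  counts (8 and 5 features) on the published importance table.
- Cumulative features are per-subject running sums over minutes of the
  wide (≥ 0.010) set.
- The classifier bank fixes small grids per base algorithm (3–5 values
  of one hyperparameter each; there is no canonical grid for this
  task, so they are kept small and documented):
  SVM C ∈ {0.1, 1, 10}; decision-tree depth ∈ {3, 5, ∞}; random-forest
  depth ∈ {3, ∞} at 100 trees; logistic C ∈ {0.1, 1, 10}; KNN
  k ∈ {3, 5, 7}; MLP hidden ∈ {16, 32} with the lbfgs solver (reliable
  at a few hundred samples). Ensembles are built over the tuned bases:
  hard Voting; Stacking with a logistic meta-learner; Bagging (10
  estimators) of the base with the best CV score; gradient Boosting
  over trees. Each repeat draws a seeded stratified 20% holdout and
  scores one 5-fold cross-validation per algorithm on the rest — a
  single CV per repeat, matching a single reported CV accuracy per
  algorithm. Over 10 repeats the modal
  (cv, test) accuracy pair — rounded to 3 decimals — is reported,
  frequency ties resolved toward the middle repeat.

## Numerical workload and threshold

W is the importance-weighted sum over the cumulative feature set, with
cumulative features inheriting their base feature's weight. W stays on
the raw weighted-sum scale — no percentage rescaling — because the
shift's maximum workload is unknown to the operator and the absolute
value is the deliverable.

Threshold enumeration uses nearest-rank percentiles (rank = ⌈p·n⌉ on
the sorted sample; the phrase "percentage position in sorted order"
denotes rank positions, not interpolation) on a 0.1% grid over 5–10%.
The low cluster contributes its p-th percentile from the top, the high
cluster its p-th from the bottom; the p minimizing the boundary gap
wins, ties to the smallest p. An epsilon in the rank computation guards
against float noise (⌈0.07·100⌉ must be 7). If the clusters do not
overlap, the gap endpoints are returned with a warning and their
midpoint is the natural threshold. The integer threshold is the
boundary-pair midpoint rounded half-up, which reproduces the published
worked example (755.78, 756.58 → 756). Grading is high iff
W ≥ threshold.

## Synthetic cohort generator

The generator is the package's test bed and defines its study
conditions:

- **Geometry:** 8 subjects × 90 minutes at 30 frames/s (the camera
  rate is configurable; the eye tracker's 380 Hz is a separate device
  and is not modeled at frame level), unitized at 1 minute → 720 rows.
- **EAR stream:** baseline 0.32 with ±0.015 uniform noise (baseline
  frames never cross the 0.25 blink criterion, and stay above the 0.3
  closure criterion so background PERCLOS is driven by events only).
  Blinks are rectangular 3–8-frame dips to EAR ∈ [0.05, 0.2] at 15/min.
  Microsleep closures (10–40 frames) appear at up to 8/min scaled by a
  drowsiness severity that follows the nondecreasing episode-rate
  schedule — this is what makes minute-level PERCLOS rise smoothly
  over the session, the way sustained fatigue manifests, instead of
  only in isolated spikes.
- **Fatigue episodes** are long closures calibrated so the fused M
  crosses 0.605 mechanistically: the closure length for a target run
  length is obtained by inverting the 300-frame window dynamics,
  accounting for the expected blink/microsleep background already in
  the window. The default episode rate ramps 0.05 → 0.5 per minute;
  run-length targets are mild-dominated ({8: 0.7, 25: 0.25, 60: 0.05})
  with depth gated by drowsiness (severe runs only at high severity),
  so mild occurrences are common, severe runs and alarms rare and
  late — the severity ordering the supervised stage is expected to
  discover. Realized runs come out somewhat longer than their targets
  because nearby blinks also occupy the PERCLOS window; the
  calibration is deliberately coarse.
- **Dropped frames:** i.i.d. Bernoulli at 6%.
- **Minute indicators:** each sensor channel is Gaussian per minute.
  Six workload-sensitive channels (blink count, both AOI dwell
  percentages, both transfer counts, respiratory rate) shift between
  regimes by `effect_size` (default 3) within-regime standard
  deviations; the remaining channels (pupil diameter, gaze/sweep
  statistics, respiratory amplitude, the gaze-duration averages) are
  stable low-CV channels that the variance prescreen is meant to
  remove. Channel levels sit inside the ranges reported for this kind
  of task (pupil 1.5–3.5 mm, ~100 gaze points and sweeps, sweep length
  ≈ 130–185 px, and so on).
- **Regimes:** one change point per subject at minute 45 ± 10 (uniform
  jitter), low before, high after, stored as `true_regime` for
  recovery tests only — no analysis stage reads it. The jitter makes
  the two regimes overlap in clock time, so correctly labeled cohorts
  still show early high-minutes and late low-minutes.

What the generator does *not* emulate: within-minute autocorrelation
of sensor indicators, cross-channel correlation beyond the shared
regime, circadian or task-content structure in the schedules, any
drift in detector dropout rate, or non-Gaussian channel noise. Passing
recovery tests therefore show that the pipeline's stages compose
correctly under the assumed two-regime structure — not that real
control-room data satisfies that structure.

## Problem sizes used in checks

The test suite runs the full pipeline at study scale (720 minute rows,
1.296M frames per cohort) for geometry, recovery and monotonicity
checks; the classifier bank runs its complete 10-repeat protocol on
the cumulative feature set at effect size 4. Oracle equivalences use
1,000 random 400-frame streams for the state machine, 300 random
windows for PERCLOS, and 100 random cluster pairs for the threshold
enumeration.

## Known limitations

- Landmark detection, live video, and proprietary tracker formats are
  out of scope; inputs are CSV streams.
- Only the two-level (low/high) workload outcome is supported; the
  level-assignment rule is undefined for K ≠ 2 and raises.
- The silhouette margin between K = 2 and K = 3 on the default cohort
  is modest (≈ 0.62 vs ≈ 0.61), mirroring how close such margins are
  in practice; a differently structured cohort (e.g. with strong
  within-regime substructure) can legitimately select K > 2 and stop
  the pipeline.
- Random-forest imputation extrapolates poorly outside the observed
  indicator range; the clamp makes this explicit rather than hiding it.
- The cumulative workload series is nondecreasing by construction when
  all weighted features are nonnegative; indicators that could go
  negative (none do by default) would break that reading.
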