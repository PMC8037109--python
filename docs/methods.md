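# Methods

This note records the models, conventions and numerical choices behind
`imurehab`, in the order data flows through the pipeline.

## Sensor model and derived signals

A recording is a uniform-grid six-channel series: accelerometer in g,
gyroscope in deg/s, default 102.4 Hz. The sensor frame has x along the
shin (distal), y mediolateral, z anterior-posterior; at rest with the shin
horizontal the accelerometer reads (0, 0, 1) g. Nine analysis vectors are
derived per sample: the six raw channels, the acceleration magnitude
‖a‖ (gravity-anchored, ≈1 g at rest), and accelerometer-only static-tilt
angles

    pitch = atan2(-ax, sqrt(ay² + az²)) ∈ [-π/2, π/2]
    roll  = atan2(ay, az)               ∈ [-π, π]

No gyro fusion (e.g. a complementary filter) is applied: a single
shin-worn IMU during slow therapeutic movement is quasi-static, so
accelerometer tilt is adequate and keeps the transform stateless and
exactly reproducible. "Magnitude" means acceleration magnitude; the
gyroscope magnitude appears separately as the segmenter's activity
statistic.

## Synthetic session generator

The generator emulates sets of discrete repetitions separated by rest.
A correct repetition is a raised-cosine pitch excursion
θ(t) = A·θ_max·(1 − cos 2πt/T)/2 over duration T, with roll flat; gravity
is resolved through (pitch, roll) into the accelerometer and the gyroscope
carries the trajectory derivatives (small-angle coupling neglected —
adequate for excursions under ~1 rad). Nominal peak excursions θ_max per
exercise: HS 0.9, IRQ 0.55, SLR 0.75, SAKE 0.85 rad — large sweeps for
heel slides and leg raises, a smaller arc for inner-range quadriceps.

Each exercise has exactly one injectable deviation, all continuous in a
severity s ∈ (0, 1] and reducing to the identity as s → 0:

- HS, *excessive hip external rotation*: a correlated roll excursion
  s·0.6·bump rides along the repetition;
- IRQ, *hip flexion lift*: an extra mid-repetition pitch bump
  s·0.45·window (the knee lifts off the support roll);
- SLR, *knee flexion lag*: the pitch profile sags mid-repetition by a
  factor (1 − s·0.55·window);
- SAKE, *incomplete extension*: the whole excursion scales by (1 − s), so
  peak range is (1 − s) of the clean repetition's.

Default severity is 0.7, surfaced in the cohort config rather than
hard-coded, since real deviation magnitudes are not quantified anywhere.

Random structure: one pseudo-random stream per subject (derived from the
cohort seed and a CRC of the subject id) carries slow between-subject
tempo and amplitude multipliers, so cohorts can be extended without
perturbing existing subjects; a per-(subject, exercise, set) stream draws
rep/rest durations, amplitudes, labels, the per-session baseline
orientation offset, and i.i.d. Gaussian sensor noise. Everything is a
pure function of the config and ids.

Three presets define the study conditions:

| preset   | sets | sub-opt. frac. | rep dur (s) | amplitude | gyro noise (dps) | orient. SD (rad) |
|----------|------|----------------|-------------|-----------|------------------|------------------|
| training | 2    | 0.5            | 3.0 ± 0.3   | 1.0 ± .08 | 1.2              | 0.02             |
| healthy  | 1    | 0.0            | 2.8 ± .35   | 1.0 ± .08 | 1.5              | 0.05             |
| clinical | 3    | 0.4            | 3.8 ± 0.7   | 0.8 ± 0.2 | 3.5              | 0.12             |

The training preset mimics balanced, supervised-clinic collection from a
heterogeneous rehabilitation population; the healthy preset an all-correct
home test cohort; the clinical preset a post-surgery cohort that moves
more slowly, with reduced and more variable range, more motion-related
noise (tremor, soft support surfaces) and larger sleeve-placement
offsets. Sensor noise differs only moderately between training and healthy
conditions because it is chiefly device-intrinsic; the clinical value
folds in motion artefact. The clinical shift is deliberately implemented
as *simultaneously* increased variance, slower tempo and higher noise —
the mechanisms that plausibly drive real-world degradation — and the
reduced clinical amplitude is the main driver of classification errors:
weak-but-correct repetitions resemble the incomplete-range deviation the
classifiers were trained to flag.

What the generator does **not** model: biomechanically faithful joint
kinematics, surface-specific artefacts beyond variance inflation,
non-uniform sampling, or labeller disagreement. Passing tests on this
generator therefore demonstrate the pipeline's internal correctness and
its qualitative lab→home→clinic behaviour, not absolute accuracies on any
real cohort.

## Segmenter

Activity statistic: centered moving SD of the gyroscope magnitude,
window 1.0 s. The gyroscope is near-zero at rest regardless of
orientation, which the accelerometer is not. The long window is needed
because a short-window SD dips at the slow-velocity crest of a repetition
and would fragment it into false rest. Rest intervals are maximal spans
below 3 deg/s; spans closer than 0.8 s merge, and each cluster's midpoint
is a reference point. Between consecutive reference points the span is
trimmed to the first/last sample whose *quarter-width-window* activity
exceeds the threshold — the short window hugs the true onset/offset, while
the long-window profile would smear boundaries ~0.3 s outward and bias
the features of automatically segmented repetitions relative to the
training segments. The trimmed primary-axis (gyro y) waveform is linearly
resampled to 128 samples, scaled to unit energy and correlated at zero lag
with the exercise template (unit-energy pointwise mean of
length-normalized training repetitions); spans scoring below 0.7 are
rejected, zero-energy spans score 0. Trimming before matching (rather
than after) makes the candidate a putative repetition, so the correlation
threshold is meaningful; linear resampling avoids the ringing of Fourier
resampling on short segments. Dynamic-time-warping similarity was
considered and rejected: it adds parameters without evidence it is needed
for single-peaked therapeutic movements.

## Feature conventions

Static features use population SD/variance (ddof 0), biased moment
estimators for skewness and excess kurtosis (defined as 0 for constant
segments), linear-interpolation quartiles, and 0 (not NaN) for empty
positive/negative subsets — classifiers require finite inputs. Dynamic
features are computed on the repetition linearly resampled to 256 samples
so that "the first 20 Fourier coefficients" index the same normalized
frequencies for every repetition; coefficients are one-sided magnitudes
(complex parts would break the 25-count). The energy-style summaries are
this package's explicit conventions, each isolated in one function:
energy is the mean-removed average power computed from the one-sided
spectrum with Parseval weights (exactly the population variance of the
resampled segment); energy ratio the lower-half-band share of non-DC
power; energy average the energy per non-DC bin; harmonic ratio the share
of the strongest bin; energy entropy the Shannon entropy (bits) of the
normalized non-DC power spectrum. Scaling a repetition by c scales
mean/SD/max/min/SAD by c and variance/energy by c² while leaving the
ratios, entropy and the pitch–roll correlation unchanged — a property the
test suite enforces.

## Classifiers and cross-validation

Hyperparameters are conventional defaults: logistic regression (lbfgs,
L2), linear-kernel SVM with C = 1, AdaBoost and random forest with 100
estimators, a depth-unlimited decision tree with min_samples_leaf = 2
standing in for the C4.5/J48 family. Standardization is fit inside each
training fold only; leave-one-subject-out folds whose training split
lacks a class are skipped with a warning and recorded. Confusion counts
are pooled (micro-averaged) across folds because a single value per
exercise is wanted. Best-algorithm selection is argmax accuracy with ties
broken by sensitivity, then a fixed roster order. "Correct" is the
positive class throughout.

## Boundary matching and summaries

Start points and end points are matched separately, one-to-one, greedy
nearest-first. A predicted start is acceptable for manual repetition k if
it lies in [start_k − 0.5 s, start_k + 0.25 s], or earlier provided it
stays strictly after repetition k−1's manual end (for the first
repetition, after the signal start); the end rule mirrors this forward.
Because repetitions last longer than the 0.25 s inward slack, the
acceptance region of each manual point is disjoint from its neighbours',
so greedy nearest-first matching provably attains the maximum-cardinality
assignment; the test suite verifies exact agreement with an exhaustive
assignment oracle on small sessions. Event accuracy is TP/(TP+FP+FN) —
the standard event-detection accuracy, bounded above by both precision
and recall.

Combined-system evaluation classifies only the repetitions the segmenter
finds: each predicted segment is paired with the maximally overlapping
manual repetition (ties to the earlier one, each manual repetition used
at most once), zero-overlap segments are dropped and counted, and
confusion counts are computed against the paired ground-truth labels.

Cohort summaries are means with 95% Student-t intervals over exercise
sets (clinical subjects contribute three sets each), clipped to [0, 100];
a single value yields a degenerate interval. Bands: excellent ≥ 90,
good 80–89, moderate 60–79, poor < 60 — the published banding leaves
(59, 60) unassigned, closed here at 60.

## Problem sizes and determinism

The reference study configuration uses 10 subjects per cohort, 15
repetitions per set, severity 0.7 and the three presets above; it
completes in about a minute on one CPU. The test suite runs the same
configuration once and exercises byte-level run-to-run determinism on a
4-subject configuration; determinism is size-independent because every
output is a pure function of (config, seed). All reported numbers are
computed at run time; the only stored values are the bundled reference
summary tables used as inputs to the table-arithmetic checks.

## Known limitations

- Classifier equivalence to the original deployment is at the algorithm-
  family level only; the original toolkit and its defaults are unknown.
- LOSOCV accuracy on the synthetic training cohort saturates near 100%
  because severity-0.7 deviations are cleanly separable at clinic noise
  levels; the generator is calibrated for the staged degradation trend,
  not for reproducing any particular published accuracy.
- Whether the original system computed spectra on raw-length repetitions,
  and which quartile convention it used, is unrecoverable; both choices
  here are documented above and isolated for substitution.
- The boundary matcher's greedy-equals-optimal argument relies on
  repetitions out-lasting the inward tolerance; pathological annotations
  with sub-0.25 s repetitions could break it (the exhaustive oracle in
  the tests would catch this).
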