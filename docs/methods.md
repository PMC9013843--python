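# Methods

This note documents the models and numerical choices in `hdwear`: the
feature-extraction conventions, the two-stage predictor, the synthetic
cohort generator and its calibration, and the limits of what results on
synthetic cohorts demonstrate.

## Signal model and preprocessing

Sensor streams are plain `t,x,y,z` CSVs (seconds; g for accelerometers,
deg/s for gyroscopes).  Loading validates strictly increasing timestamps
with ≤1% jitter, finite values, and a sampling rate of at least 32 Hz (the
floor needed to represent the 16 Hz band edge); the rate itself is inferred
from the median timestamp interval.  Task windows are half-open
`[start, end)` and come from manual annotations in a JSON manifest — the
walking windows delimit straight passes only, so turn detection is out of
scope.  Segments shorter than 3 s are flagged with a warning.

Each axis is filtered with a 5th-order Butterworth bandpass, 1–16 Hz,
applied as a single forward pass through second-order sections.
A Butterworth response is the default reading of an otherwise unspecified
bandpass; a zero-phase double pass (`zero_phase=True`) is available but
doubles the effective order, so it is off by default.  The filter state is
initialized at steady state for the first sample's level (`sosfilt_zi`), so
a DC offset — gravity, most importantly — does not ring through the start
of the segment; the first and last second of each filtered segment are
discarded as well.  The three filtered axes are then combined per sample
into the Euclidean norm.  Filtering is linear and the norm is
rotation-invariant, so a constant re-mounting rotation of the sensor leaves
the magnitude signal unchanged; the test suite checks this to 1e-6.

## The thirteen statistics

Per magnitude signal: RMS, absolute maximum, sample SD (n−1); peak
statistics from strict local maxima with a plateau counted once at its
first sample, and no height or prominence threshold — small noise maxima
are counted, as a threshold-free peak finder would; mean/SD/max/min peak
height, mean/SD inter-peak interval (seconds).  With no peaks all six peak
statistics are 0; with one peak the SDs and intervals are 0; both cases are
logged as degenerate rather than dropped so the feature matrix stays
rectangular.

Spectral estimates use Welch's method with 4-s Hann windows and 50%
overlap — long enough for ~0.25 Hz resolution, short enough to average
several windows over a 10–30 s segment.  The mean normalized frequency f̄
is the power-weighted mean (spectral centroid) of the periodogram
restricted to 1–16 Hz; an all-zero signal yields the band midpoint 8.5 Hz
with a degeneracy flag.  Band powers are means of the periodogram density
over three 1-Hz windows centred at f̄−2, f̄ and f̄+2, clipped to 1–16 Hz
(an empty clipped band contributes 0).  This convention reproduces the
worked example of 7–8 / 9–10 / 11–12 Hz at f̄ = 9.5; the alternative
reading — three contiguous 2-Hz bands tiling [f̄−3, f̄+3] — is available
via `band_convention="contiguous"` but does not match that example.

Walking features are averaged at the feature level: the 13 statistics are
computed per straightaway and arithmetically averaged across the five
passes (not computed on concatenated signal).  Totals: 104 features per
task, 312 per subject.

## Two-stage prediction

**Selection.**  Inside every cross-validation round, features are z-scored
with training-fold statistics and screened by an L1 path (100 log-spaced
penalties down to alpha_max·1e−3).  The penalty minimizing inner 5-fold CV
error is chosen, with the CV repeated 5 times and averaged — a single split
is too noisy at n≈27 — then the penalty is tightened along the path until
at most 19 features remain (at least one is always kept).  Class labels are
screened with a plain LASSO on the 0/1 indicator, the classical screening
approach; an L1 logistic path is available via `classify_loss="logistic"`.
All-constant columns are excluded before fitting.

**Stage 1.**  LDA, linear SVM (C = 1), or KNN (k = 5, Euclidean) on the
selected, standardized features.  LDA uses Ledoit–Wolf shrinkage
(`solver="lsqr", shrinkage="auto"`): with up to 19 features and ~27
training subjects the sample covariance is ill-conditioned, and the
unregularized discriminant was observably unstable.

**Stage 2.**  Trained on symptomatic subjects only.  Families: linear SVR
(C = 1, ε = 0.1·SD(y)); decision tree (minimum leaf 2, cost-complexity
pruning chosen by inner 3-fold CV over the pruning path); Gaussian process
with an exponential (Ornstein–Uhlenbeck, Matérn ν = 1/2) kernel, constant
scale and white-noise terms, hyperparameters by marginal-likelihood
maximization with 5 restarts, targets normalized.  Predictions are
continuous and clipped to [0, r]; integer rounding is available but off by
default, since nMAE is computed on real-valued errors.  A constant training
target short-circuits to predicting that constant.

**Combination.**  Subjects LOO-classified as controls are scored 0.
True HD subjects classified as HD receive their stage-2 LOO prediction; a
misclassified control receives a prediction from the stage-2 model fit on
all symptomatic subjects (its own data never enters stage-2 training).
Misclassified controls are included in the error analysis.  The composite
(range 60) can be predicted either directly by a single model or as the sum
of the seven per-subscore predictions; both strategies are exposed for
comparison.

LOO is one round per subject — n rounds for n subjects.  Standardization
and selection are refit per round; a probe test verifies that corrupting
the held-out row cannot change what a round selects.

## Evaluation

Classification: accuracy, sensitivity (TP/positives), specificity
(TN/negatives), HD positive; a rate whose denominator class is absent is
reported as NaN.  Regression: nMAE = (1/(N·r))·Σ|y−ŷ| as a proportion and
as percent of score range.  Model comparison: two-sided Mann–Whitney U,
exact null for tie-free samples up to n = 20, tie-corrected normal
approximation otherwise; the exact path is cross-checked in the tests
against brute-force enumeration of rank arrangements.  Error–covariate
association: Pearson r with two-sided t-test p; zero-variance input reports
NaN.  Feature stability: features selected in ≥50% of rounds (boundary
inclusive), sorted by frequency.  Quartiles use linear (type-7)
interpolation.

## Synthetic cohorts

No recordings are distributed, so the generator is a first-class module
that emulates the study structure: 14 HD + 14 controls by default, 100 Hz
sampling (a choice — the device rate is not documented), sit 30 s, stand
30 s, five 12-s walks separated by 5-s turn gaps, eight streams per
subject, gyroscopes on forearms and sacrum only, per-subject random
constant mounting rotations, white Gaussian noise (0.015 g, 1 deg/s per
axis), gravity on the accelerometer.

Subscores: controls are all-zero by protocol.  Each HD subject draws a
latent severity p ~ U(0.2, 0.8); every 0–4 item is Binomial(4, p); total
chorea and dystonia each sum five body-site items (arms, legs, trunk).
One HD subject per cohort is drawn at p = 0.08, deliberately overlapping
the control boundary so stage 1 is not vacuously easy.

Severity maps (all monotone; slopes are the calibrated defaults in
`severity_profile`):

| Subscore | Signal effect |
| --- | --- |
| bradykinesia | cadence 1.9 − 0.11·score Hz; walking amplitude ×(1 − 0.07·score) |
| gait | stride-frequency jitter CV 0.02 + 0.04·score; step-amplitude CV 0.04 + 0.06·score; mediolateral walk amplitude ×(1 + 0.35·score); small cadence reduction |
| tandem gait | standing sway ×(1 + 0.35·score); extra stride jitter |
| arm rigidity | arm-swing amplitude ×(1 − 0.17·score) on that forearm |
| chorea (per site) | Poisson bursts at 0.12·score /s of damped 3–10 Hz oscillation, amplitude ~0.3 g, random 3-D direction, in every task |
| dystonia (per site) | one-sided 0.1–0.5 Hz envelope drift, depth 0.3·score, on that sensor's postural sway (sit/stand), plus a sub-band offset drift |
| composite | postural sway amplitude ×(1 + 0.05·composite) in sit/stand |

Design notes.  The composite-driven sway term models the global postural
instability of HD and gives every symptomatic subject a group-level
signature on common channels, so classification does not hinge on any one
limb's chorea pattern.  The dystonia envelope drifts upward from baseline
(sustained posturing adds muscle activity), which makes mean amplitude
linear in the drift depth; it is expressed in the postural tasks, where
sustained posturing dominates, and deliberately not during walking so that
gait decoding is not confounded.  Sway frequencies (1.2–2.0 Hz) sit inside
the analysis band.  Walking is synthesized from an integrated
instantaneous-phase oscillator (thighs at cadence, sacrum at twice cadence,
forearms as anti-phase arm swing), so stride-timing jitter broadens the
spectral line exactly as timing variability should.  Gyroscope streams
share the latent phase and severity components with the accelerometers but
have their own amplitudes and noise, so the two modalities are correlated
but not redundant.

All randomness derives from one master seed through named sub-streams
(subscores, rotations, per-sensor signals, age), so cohorts are bitwise
reproducible and components can be varied independently.

**Calibration.**  Effect sizes were calibrated once, before freezing, so
that the synthetic task is non-trivial (sensor noise, random mounting
rotations, one boundary-severity subject, overlapping severity effects)
while the study-level performance bounds are achievable.  On master seeds
1, 2, 7, 11 and 42 the frozen configuration gives stage-1 LDA LOO accuracy
between 96.4% and 100% (the boundary subject accounts for nearly every
miss), full-model composite nMAE 1–3%, and stage-2 GP nMAEs of 4.5–7.5%
(gait) and 4.5–8.5% (total dystonia).

**What this does and does not show.**  Passing bounds on synthetic cohorts
demonstrates that the pipeline is implemented coherently end to end: the
features expose the severity information the generator encodes, selection
and cross-validation are leak-free, and the models recover monotone
severity maps at n = 28.  It does not validate the method on real patients:
the generator's severity-to-signal maps are smooth and monotone by
construction, its noise is white, inter-subject anatomy and rater noise are
absent, and subscore effects are cleanly separable by design.  Real
performance claims require clinical recordings.

## Numerical details and degenerate inputs

Feature extraction is a pure function: identical input gives bitwise
identical output.  Peak and spectral degeneracies are logged, never raised.
A constant regression target short-circuits the regressor; an all-control
cohort raises an explicit error in stage 1, as does any training fold with
fewer than two subjects of either class.  The LASSO path suppresses
coordinate-descent convergence warnings at the smallest penalties, which
the selected penalty never occupies.  Problem sizes in the test suite
follow the study design (28 subjects, 14 per group) for the headline
checks, with smaller cohorts (4–12 subjects) for structural and interface
tests.

## Known limitations

No gravity-component estimation or sensor fusion; no automatic turn
detection; no multiple-testing correction across subscores; the
"24 training rounds" question (the study text mentions 24 rounds for 28
participants) is resolved as one round per subject; hyperparameters beyond
the documented defaults are not searched.
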