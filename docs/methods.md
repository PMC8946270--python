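# Methods

This note documents the models and procedures implemented in `stridelab`,
the defaults and why they were chosen, and what the synthetic validation
does and does not establish about real insole data.

## Gait model and conventions

One stride runs from a heel strike (HS) to the next HS of the same foot.
Stance is HS→TO, swing TO→next HS. Within stance, the opposite foot's TO
and HS bound the two double-support periods: first double support
DS1 = [HS, opposite TO), single support = [opposite TO, opposite HS),
second double support DS2 = [opposite HS, TO). The seven phases are the
standard clinical partition: loading response `[HS, oppTO)`, mid stance
`[oppTO, HR)`, terminal stance `[HR, oppHS)`, pre swing `[oppHS, TO)`,
initial swing `[TO, FA)`, mid swing `[FA, TV)`, terminal swing
`[TV, next HS)`. All intervals are half-open, times in seconds, sample
indices 0-based.

Sensor conventions: accelerometer in g with +1 g on z for a flat stationary
foot, gyroscope in deg/s with y the sagittal (pitch) axis, x the walking
direction; signals clip at ±8 g and ±1000 deg/s, sampling at 100 Hz.

## Synthetic generator

The generator emulates the periodic, stance-quiet / swing-active character
of foot-worn inertial signals, not foot biomechanics. The foot rotates
about one fixed body axis dominated by pitch; its angular rate is a sum of
raised-cosine pulses — a slow plantar-flexion pulse from heel rise to toe
off, a dip at TO, the dominant positive swing peak at FA, and a dip at HS —
whose areas cancel over each stride so the foot returns flat. Forward
velocity is likewise pulse-based (push-off after HR, a main swing pulse, a
zero-net-velocity jolt at HS) and integrates exactly to the profile's
stride length per stride; vertical clearance and lateral sway are periodic
position bumps. The accelerometer output is the body-frame specific force
implied by this trajectory, so the strap-down ZUPT-EKF can in principle
recover the stride length exactly up to discretisation.

Key defaults (`GaitProfile`): cadence 115 steps/min, stance 60%, first
double support 10% of the cycle, HR at 50% of stance, FA/TV at 45%/75% of
swing, stride length 1.0 m. These sit in the range reported for older adult
walkers. Waveform amplitudes (swing peak ≈ 300 deg/s, HS jolt 3 m/s²,
5 cm clearance) are design choices: the underlying study reports no
quantitative amplitudes, only the qualitative waveform shape, so amplitudes
were fixed once at values that make every event detectable and every
feature non-degenerate.

`asymmetry` scales right/left stance percent, DS1 and stride length by
`1 ± a/2`, so the temporal symmetry indices equal `a` by construction.
Noise is white Gaussian per channel with SD expressed as a fraction of that
channel's noise-free peak ("low noise" in tests = 0.02). Cohort generation
jitters each subject's profile log-normally (default sd 2%); stance and DS1
receive half that sd because double-support durations are small differences
of those fields — full jitter is amplified roughly fifteen-fold there and
routinely produces degenerate pre-swing windows that no detector could
segment.

What the simulator does *not* model: turning, stairs, treadmill gait, soft
tissue artefact, sensor bias/drift, cross-axis misalignment, or any
disease-specific waveform change beyond schedule/asymmetry shifts. Passing
tests therefore demonstrate algorithmic correctness against a known ground
truth, not clinical performance on patient data.

## Event detection

The dominant stride period comes from the autocorrelation of the 0.3–3 Hz
band-passed sagittal gyro; a bout whose implied cadence falls outside
40–160 steps/min is rejected outright. Mid-swing peaks are found on the raw
gyro (height 40% of the 99.5th percentile, minimum spacing 0.6 stride
periods); TO is the gyro minimum in the 0.45-period window before each
peak, HS the minimum after it, both refined to sub-sample resolution by
parabolic interpolation. FA is the swing peak itself; TV the first downward
zero crossing after it. HR is the onset of the push-off transient: the
first sample in late stance where the 1.5 Hz high-passed forward
acceleration exceeds max(6·MAD of mid-stance, 0.02 g). Equal-valued minima
resolve to the earlier sample; a missing transient falls back to
mid-stance. The first and last strides of every bout are discarded.

On simulated data this detector is effectively exact for HS (the gyro
minimum coincides with the modelled event) and within a millisecond or two
for TO; at 2% noise the HS/TO mean absolute error is ≈ 3 ms, an order of
magnitude inside the 30 ms accuracy cited for published foot-worn
detectors. HR detection is biased late by tens of milliseconds (onset
thresholds trail pulse starts); nothing downstream requires HR at
millisecond accuracy.

## Spatial–temporal parameters

All temporal quantities are computed per stride from the event times
(stance = TO − HS, DS1 = oppTO − HS, etc.), averaged over strides, and only
then combined into percents, symmetry indices and cadence
(120 / mean stride time; this is robust to a dropped event, unlike step
counting). Strides whose opposite-foot events do not interleave correctly
are skipped. Whether one should average per stride or pool strides before
deriving ratios is genuinely ambiguous in the clinical literature;
per-stride-then-average was fixed here. "Double support first phase right"
is defined relative to the right foot's own HS.

Stride length: zero-velocity samples are those where 5-sample moving
averages of gyro magnitude and |‖acc‖ − 1 g| stay below 15 deg/s and
0.08 g — standard foot-mounted thresholds, configurable. A 9-state
error-state EKF (position, velocity, attitude error) propagates strap-down
integration and applies zero-velocity pseudo-measurements (σ = 0.01 m/s)
during masked samples; attitude initialises by gravity alignment on the
first foot-flat interval, and since heading is unobservable only the
horizontal displacement magnitude between consecutive zero-velocity
midpoints is reported. Process noise defaults: σ_acc = 0.02 g,
σ_gyro = 0.2 deg/s. On noise-free simulation the estimate lands within
2% of truth (discretisation of the 100 Hz strap-down integration accounts
for most of it), within 5% at low noise.

## Descriptive features

Statistics are computed on the raw (un-resampled) samples inside each phase
window, per stride, then averaged over strides. The 100-sample spline
normalisation exists for waveform comparison and sequence-model input, not
for the statistics. Conventions fixed here because the verbal definitions
admit several readings: SD is the sample standard deviation (ddof = 1);
kurtosis is Pearson moment kurtosis (normal = 3); skewness the biased
Fisher–Pearson g1; MMgr ("gradient from max to min") is the signed slope
(max − min)/(t_min − t_max) in units/s, 0 for constant segments; ties for
extrema locations resolve to the earliest sample. Segments shorter than 2
samples are skipped per stride; a feature with no valid stride is NaN and
marks the vector incomplete.

## Classification and cross-validation

Preselection uses Welch's two-sided t-test (the pooled-variance variant is
available); the k = 100 smallest-p features are kept, ties broken by
feature index. Classifier defaults follow the reference setup: RF with 50
trees, depth 30, √p features; XGBoost gbtree / binary:logistic with
eta 0.018, depth 15, gamma 0.009, subsample 0.98, colsample_bytree 0.86
(tree count is unspecified there; 100 is used); SVM linear/RBF with
gamma 1.0, C 5.0, z-scored on the training fold since an RBF at gamma 1.0
is scale-sensitive. Leave-one-pair-out CV holds out one subject per class
per fold; selection is refit inside each training fold to avoid leakage
(whether the original analysis did so is unstated; global selection would
look optimistic). Accuracy is the mean over folds; precision/recall/F1 are
computed on pooled out-of-fold predictions because two-sample test sets
make per-fold versions degenerate. A probability tie at 0.5 predicts the
control class.

## Importance and Shapley values

Gini importance is the ensembles' impurity-decrease importance;
permutation importance is the mean accuracy drop over seeded column
shuffles. Shapley attributions use an interventional value function
(coalition features from the explained sample, the rest marginalised over a
background set): exact subset enumeration up to 12 features, antithetic
permutation sampling beyond (each permutation telescopes, so the
local-accuracy identity Σφ + base = f(x) holds exactly at any sampling
budget), and XGBoost's native TreeSHAP contributions for boosted trees.
Tree-model attributions are reported on the margin (log-odds) scale, where
magnitudes around 1 are typical; probability-scale attributions are
available via the `scale` argument. Fold-averaged rankings take each
feature's mean score over the folds in which it was selected; the top-k
sweep retrains every model family on the top-k ranked features over a
configurable k grid (default 2–10, 15–20, 100).

## Numerical choices and degenerate inputs

Pulse anchors snap to the sample grid, making noise-free signals exactly
periodic (bit-identical interior cycles) and simulations reproducible to
the byte under a fixed seed. Kurtosis/skewness of constant segments are
defined as 0. Zero-variance features receive p = 1 in selection. Profiles
whose stance/DS1 combination leaves a second double support below 2% of
the cycle are rejected at validation because no 100 Hz window can represent
the pre-swing phase. Default cohort sizes in the pipeline configuration
(21 per group) and the test suite's smaller cohorts (3–10 per group,
12–36 s bouts) were chosen so every check runs on a single CPU in minutes
while keeping ≥ 8 analysable strides per subject.

## Known limitations

- The event detector is defined and validated against the simulator's
  ground truth, not against the time–frequency detector used with the
  original clinical system; on real data its HR onset in particular should
  be re-validated against a reference system.
- The EKF reports only horizontal displacement magnitude; walking must be
  approximately straight for "stride length" to be meaningful.
- Margin-scale Shapley values are not comparable across model families.
- The published patient-cohort accuracies cannot be reproduced here: the
  underlying recordings are unavailable, and no synthetic cohort stands in
  for real between-group effect structure.
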