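# Methods

## The synthetic gait model

A walking session is a sequence of contiguous gait cycles anchored at right
heel strikes. Cycle `k` has duration `T_k` drawn from
`Normal(mean_T, cv·mean_T)` (clipped to ±50 %), where `mean_T` depends on
the instructed speed class (defaults 1.3 / 1.1 / 0.9 s for slow / normal /
fast), a per-subject scale (`Normal(1, 0.05)`), and a mild per-rating
slowing (2 % per clinical rating point). Within a cycle, the seven
remaining events sit at configurable phase fractions

| event | meaning            | fraction |
|-------|--------------------|----------|
| t02   | left toe off       | 0.12 |
| t03   | right toe strike   | 0.20 |
| t04   | right heel off     | 0.40 |
| t05   | left heel strike   | 0.50 |
| t06   | right toe off      | 0.62 |
| t07   | left toe strike    | 0.65 |
| t08   | left heel off      | 0.90 |

which are normative gait-phase proportions (loading response ≈ 12 % of the
cycle, stance ≈ 62 %, single support ≈ 38 %). Each event receives Gaussian
timing jitter (base std 4 ms). The impairment model inflates the jitter of
the loading-response events (t02, t06) by `1 + 0.75·rating` and of the
pre-swing events (t04, t07) by `1 + 0.5·rating`, adds left/right cadence
asymmetry (1 % per rating point, implemented as an early shift of the left
heel strike) and, in the OFF medication state, amplifies the whole effect by
1.25 for rated subjects. These coefficients are the study conditions of the
cohort; cycles that violate the event order after jitter are redrawn (up to
100 times, then the generator fails loudly).

The default cohort mirrors a typical movement-disorders gait protocol: 19 subjects × 2
medication states × 3 speeds × 2 repetitions = 228 sessions, with clinical
gait ratings distributed 0:4, 1:11, 2:2, 3:2 over subjects and
`impaired = rating > 0` as the session label. Stride counts per session
vary around 16 (more strides at slow speed, fewer at fast), emulating a
fixed 10 m out-and-back course.

### Rendering

**Insole (100 Hz).** Heel cells (rear five) load during [heel strike, heel
off] and toe cells (front six) during [toe strike, toe off] of each foot,
with linear loading ramps (default 0.10 s, a physiological heel-loading
rise time) positioned so the envelope crosses the detection level exactly
at the event time. Total force is the area-weighted cell sum; the
longitudinal center of pressure migrates heel→toe through stance. A virtual
left stance before the first cycle and a virtual right heel strike after
the last make all generated cycles completable by the detector instead of
losing the two edge cycles. Additive Gaussian noise per channel (default
pressure std 0.05 N/cm², ~1 % of the stance peak).

**Ankle IMUs (59.5 Hz).** Per stride the gyroscope Z axis carries one
positive mid-swing Gaussian lobe (amplitude ~200 dps, σ = 60 ms), a −60 dps
dip at that foot's toe off and a −30 dps dip at its heel strike (σ = 20 ms);
the accelerometer magnitude spikes at heel strike over a 1 g gravity
baseline. Default gyro noise std 3 dps.

### What the generator does not emulate

No turns, freezing of gait, shuffling, festination, or non-walking
activity; no biomechanically exact force magnitudes or double-bump vertical
ground-reaction profiles; no sensor drift, saturation, or inter-device
clock skew; amplitude distributions are normative, not fitted to any real
recording. Passing tests therefore demonstrate that the *pipelines* are
correct and internally consistent — they do not certify performance on
clinical data, whose artifacts (turn segments in particular) are known to
degrade single-foot agreement.

## Insole pipeline

Preprocessing low-pass filters the pressure channels with a zero-phase
4th-order Butterworth and subtracts each cell's minimum (baseline). The
default cutoff is 20 Hz: a zero-phase 10 Hz filter visibly smears a 0.1 s
loading ramp and shifts its 5 %-of-peak crossing by >10 ms, i.e. more than
one sample of event-timing bias, while 20 Hz keeps the shift below 5 ms and
still suppresses sensor noise. Normalization (none / session peak / body
weight) is recorded in provenance; default none.

Contact detection per region uses a threshold of 5 % of the session's 95th
percentile regional force (scale-free; absolute-Newton override available)
with a 20 % hysteresis band: contact asserts above the threshold and
releases only below 0.8× of it, so chatter around the threshold cannot
emit event bursts. Event *times* are always interpolated at the nominal
threshold crossing (searched near the state transition) — reporting the
hysteresis-level crossing instead would bias every release event late.
Events closer than 50 ms to their predecessor of the same kind are
debounced. Cycles are assembled between successive right heel strikes;
a cycle is kept only if each of the other seven events occurs exactly once,
in order, inside it, and a successor left toe-off exists; everything else
is counted in diagnostics and skipped.

The right-single-support formula in printed versions of this feature catalogue duplicates the
left-stance formula; the default here is the biomechanically consistent
`a01 = t05 − t02` (right single support = left swing, the mirror of
`a02 = t01′ − t06`), which also preserves the identity `a02 + a04 = a09`.
`printed_formula=True` reproduces the printed formula for comparability.
Cadence `a14 = 1/(t02′ − t01)` is kept in cycles/s exactly as defined;
`cadence_steps_per_min` converts (×120) but is never substituted silently.

## IMU pipeline

Walking bouts: manual intervals pass through verbatim; automatic mode
thresholds the 1 s moving RMS of the gyro magnitude at 30 dps, merges gaps
< 1 s and drops bouts < 3 s. Event detection implements the adaptive
mid-swing threshold `max(50, 0.3·max(s_z))` dps with min peak distance
0.5 s and min width 0.1 s; the toe-off threshold (15) and initial-contact
threshold (5) are read as dip depths on the inverted signal, with the TO
dip required before and the IC dip after each mid-swing peak within 0.5 s;
strides missing either dip are dropped and counted. No resampling;
sub-sample peak interpolation is off by default, so event times carry
≤ half-sample (≈8 ms) quantization.

Stance + swing = cycle holds exactly by construction (stance of cycle k
pairs with the following stride's swing). Walking cadence follows the
insole convention 1/(t02′ − t01) computed from the IMU's own events: the
anchor is a right initial contact, the closing event the first left toe-off
after the next right initial contact. Single support of one foot is the
contralateral swing. Energy features integrate the squared signal over the
bout (`Σ x²·Δt`); accelerometer energies use median-removed axes so the
gravity baseline does not dominate. Range of shank motion integrates the
gyro Z axis over each swing (degrees). "Normalized stride length" is a
declared surrogate — swing angular excursion × a leg-length factor
(default 1/90) — and the walking-speed proxy multiplies it by cadence;
both are labelled as surrogates in the output metadata. Double support and
loading response are deliberately not computed from IMU data (they would
need both sensors fused on a common clock).

## Agreement analysis

Cases with fewer than 3 steps in either system are excluded (boundary
exclusive: 3 steps is retained). Per feature, IMU values are min–max
scaled onto the insole range (affine, so Pearson r is untouched);
differences (insole − IMU) beyond 3 robust-z units (MAD-scaled, std
fallback when the MAD degenerates) are flagged, excluded from r and ICC,
and retained as marked points in the Bland–Altman statistics. ICC(3,1) is
computed from the two-way ANOVA mean squares,
`(MSR − MSE)/(MSR + MSE)` for k = 2 raters, pooled over all retained
sessions (headline) *and* per speed class, since the source description of
"separate data classes" is ambiguous; both are reported. Bland–Altman
limits are mean ± 1.96·SD of the differences.

## Classification

Only normal-speed sessions enter the feature matrix (76 in the default
cohort). Labels are `rating > 0`; groups are subjects. Cross-validation is
subject-grouped stratified k-fold (default 5); when the minority class is
carried by fewer subjects than the requested folds, the fold count is
reduced (with a warning) rather than allowing a single-class test fold —
with 4 unimpaired subjects the default cohort runs at 4 folds.
Standardization lives inside each model pipeline and is fit on training
folds only. Hyperparameters are library defaults (RBF-SVM with probability
outputs; 100-tree ensembles), pinned in config and untuned. Metrics
(AUC, accuracy, F1, precision, recall; impaired = positive class) are
averaged over folds with their dispersion.

Feature importance is model-agnostic permutation importance evaluated on
held-out folds and averaged. It is scored with log-loss rather than AUC:
the feature set contains many mutually redundant discriminative columns
(every loading-response statistic correlates with its percentage and its
contralateral twin), so permuting any single one leaves a strong model's
held-out *ranking* perfect and AUC-based importances collapse to all-zero
ties, while the probability degradation remains visible to log-loss.
Constant features score exactly zero.

## Numerical and reproducibility notes

- All randomness streams from one master seed; per-session generators are
  keyed by CRC-32 of the session identifier, so cohorts are reproducible
  under subsetting and across interpreter runs.
- Report files carry no timestamps and cohort manifests store relative
  paths, so identical config + seed runs are byte-identical.
- Canonical CSV dialect: comma-separated, "." decimal, header row, floats
  at six decimals; write(read(x)) is byte-identical for canonical files.
- Degenerate inputs fail loudly and specifically: constant IMU samples
  cannot be range-scaled, zero-variance columns cannot be correlated,
  sessions without completed cycles raise a distinct "no steps" error, and
  all-zero pressure channels warn and pass through.
- Problem sizes used by the test suite and acceptance script — 12-cycle
  noise-free sessions for event recovery, the 228-session default cohort
  for agreement, the 76-session normal-speed cohort for classification,
  20 label permutations for the chance control — match the study-shaped
  defaults above.

## Known limitations

- The insole event detector assumes the canonical heel-first contact
  pattern; toe-first (equinus) gait would be flagged as abnormal
  transitions rather than segmented.
- Agreement near r ≈ 1 on synthetic data reflects the shared-truth design;
  real paired recordings add independent sensing errors and annotation
  ambiguity that lower r and ICC.
- The impairment classifier is binary by scope; severity grading (0–4)
  and medication-state recognition are out of scope.
- IMU event timing is limited by the 59.5 Hz grid; enabling sub-sample
  interpolation would reduce but not remove this quantization.
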