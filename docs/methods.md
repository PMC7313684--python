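# Methods

This note documents the models, numerical choices and limitations behind
`myogest`: what the synthetic acquisition emulates, how each pipeline stage
is defined, and which design decisions were genuinely open.

## Synthetic sEMG model

Surface EMG recorded by a ring of eight forearm electrodes is modelled, per
channel *c*, as

```
x_c(t) = quantize( n0 · w_c(t) + g_c · A(t) · v_c(t) )
```

where `w_c` and `v_c` are independent zero-mean Gaussian carriers
band-limited to [20, 0.45·fs] Hz and normalized to unit RMS, `n0` is the
rest-noise RMS (`noise_floor`), `g_c` the per-channel gain of the gesture
being performed, and `A(t)` a trapezoidal activation envelope. Quantization
rounds half away from zero and clips to the 8-bit range [−128, 127],
matching an armband-style integer stream. Because the carriers have unit
RMS, `noise_floor` and the profile gains are both expressed directly as RMS
amplitudes in quantization counts.

**Trial structure.** A trial lasts `duration_s` (default 4 s at
fs = 200 Hz, 800 samples): rest for `rest_fraction` (default 0.25) of the
trial at each end, linear 0.25 s ramps, and a plateau between them. This
reproduces a rest→gesture→rest repetition with enough rest for baseline
estimation and enough plateau for the envelope to settle.

**Gesture profiles.** Each gesture activates a contiguous electrode group.
The four committed profiles (RMS counts per channel) place close/open on
strongly overlapping flexor-side channels (cosine similarity 0.94) and
wave-in/wave-out on partially overlapping extensor-side groups (0.82).
The overlap is deliberate: grasp-gesture confusion is the dominant error
mode in practice, and a generator with orthogonal profiles would make the
classification problem trivially easy at any noise level. No public
recording of this acquisition exists, so the profiles are a package
convention, not measured data.

**Population and repetition variability.** `generate_dataset` draws, per
participant, a per-channel multiplicative log-normal jitter of the profile
gains (scale `participant_variability`, default 0.3 — inter-subject
anatomy and electrode placement), and, per repetition, a common-mode
log-normal effort factor (scale `trial_variability`, default 0.35 —
contraction strength varies between repetitions while the cross-channel
pattern of a gesture is preserved). The effort factor matters
qualitatively, not just quantitatively: without it, class information is a
set of stable per-channel amplitude thresholds, which structurally favours
axis-aligned decision-tree splits; with it, absolute amplitudes drift
between trials and classifiers must exploit the joint channel pattern,
which is where margin-based methods earn their advantage. Defaults put the
30-trial protocol in the low-to-mid-90s accuracy range with a consistent
SVM > tree gap of several points.

**Seeding.** A master seed spawns one `SeedSequence` child per participant
(profile jitter) and one per trial (effort factor, then the trial's carrier
seed), so any single trial is reproducible without regenerating the
dataset, and a fixed master seed yields bit-identical datasets.

**What the generator does not model:** motor-unit action potentials,
electrode-skin impedance, motion artefacts, fatigue or electrode shift
within a session, and inertial (IMU) channels. Passing tests on this data
demonstrate the pipeline's correctness and its behaviour under amplitude
variability — not performance on physiological recordings.

## Preprocessing

Per channel: mean removal; band-pass; rectification; envelope.

- **Band-pass**: Butterworth, design order 4 (8 poles as a band-pass),
  20–450 Hz requested. At fs = 200 Hz the 450 Hz edge is unrealizable; the
  upper cutoff is clamped to 0.45·fs (90 Hz) with a logged warning, once
  per distinct (cutoff, fs) pair. The 20 Hz edge — the physiologically
  critical one, removing movement artefact and baseline drift — is always
  preserved; the sampling rate must satisfy fs > 2·low_cut.
- **Zero-phase application**: forward–backward (`sosfiltfilt`) with
  reflective padding, so envelopes are not delayed relative to the raw
  burst (cross-correlation peak at lag 0) and 4 s records show no startup
  transient. Single-pass filtering is available via `zero_phase=False`.
- **Envelope**: 2nd-order Butterworth low-pass of the rectified signal,
  cutoff 6 Hz (exposed in the config), zero-phase, clipped at zero from
  below. 6 Hz tracks force-level dynamics while suppressing carrier ripple
  at 200 Hz sampling.

## Features

Per channel of the envelope (the stage that reflects muscle force; the
rectified or filtered stages are selectable via `feature_source`):

- **AR(8) coefficients** under the convention x(t) = Σ aₖ x(t−k) + e(t),
  fitted with Burg's recursion. Burg was chosen because its reflection
  coefficients are bounded by 1, guaranteeing a stable model on every
  input — including short streaming windows — where least-squares fits can
  produce unstable poles. An exactly constant signal is a defined
  degenerate case (zero coefficients, zero residual variance) rather than
  an error. Correctness is guarded in the tests by two independent
  oracles: an OLS lag regression (primary; well-conditioned even for
  repeated roots) and Yule-Walker (secondary, on benign configurations).
- **MAV** (mean absolute value) and **SD** (sample standard deviation,
  divisor n−1).

Layout: `[a_1..a_8, MAV, SD]` per channel, channels 1..8 concatenated →
80 entries. Unpacking to per-channel blocks and repacking is the identity.

## Classifiers

Published hyperparameters, implemented over scikit-learn estimators:

| kind | estimator | fixed parameters |
|------|-----------|------------------|
| ann | `MLPClassifier` | hidden (116, 48), tanh, LBFGS, max_iter 500 |
| svm | `SVC` | RBF, C = 80, γ = 0.04, one-vs-one (6 binary problems for K = 4) |
| dt | `DecisionTreeClassifier` | Gini, min_samples_split 2, min_samples_leaf 2 |

**Feature scaling.** AR coefficients (order 1) and MAV/SD (tens of counts)
live on incompatible scales, so SVM and ANN inputs are rescaled using
training-set statistics only. The default is min–max scaling to [0, 1]: a
*fixed* RBF width γ = 0.04 presumes a bounded feature scale, and under
per-feature unit variance (z-scoring) the squared distances of
80-dimensional vectors concentrate near 2·80 = 160, collapsing kernel
values to ≈ e^(−6.4) and reducing the SVM to memorization. Min–max keeps
typical squared distances of order a few units, where γ = 0.04 defines a
smooth kernel. Z-scoring remains available (`scaling="zscore"`), and the
scale-invariant tree bypasses scaling entirely.

## Evaluation protocol

30 trials per classifier; each trial draws a fresh stratified 80/20 split
and re-seeds the classifier (both sub-seeds spawned deterministically from
the master seed — the trial-to-trial spread reflects both sources).
Summaries report mean ± SD (n−1) of train and test accuracy. Confusion
matrices are row-normalized percentages over true classes, accumulated
across all 30 test sets.

Pairwise comparisons use the two-sided **Welch** t-test — accuracy
variances differ markedly between classifiers, making the pooled-variance
test unsafe — over the family of the three classifier pairs, corrected
with the step-down **Holm** procedure at α = 0.05. The degenerate case of
two identical constant samples is defined as (t, p) = (0, 1).

## Streaming runtime

A continuous stream is preprocessed in full; activity is any interval
where the max-across-channel envelope exceeds `onset_threshold` (default
3×) times the rest-baseline RMS estimated from the first `baseline_s`
(default 0.5 s, guaranteed rest by the trial protocol). Active runs merge
across gaps shorter than `hangover_s` (0.3 s) and must last at least
`min_active_s` (0.3 s).

Classification runs on trailing windows (default 1.0 s, hop 0.1 s; the
200-sample window comfortably satisfies the AR fit's n > 2m requirement).
Only windows fully inside an active segment are classified — a window
straddling the onset mixes rest and activity and only adds label flicker.
Within a segment, the first run of `vote_k` (default 3) consecutive
agreeing decisions emits a single event carrying that label, extending to
the segment end: one stable actuation command per detected gesture, with
emission latency at most `window_s + vote_k·hop_s` after the first
fully-active window. Models intended for streaming are trained on
window-length crops centred on each training trial's active segment
(`windowed_training_set`), so the training distribution matches what the
classifier sees at run time.

## Problem sizes and runtime

The committed protocol sizes are the acquisition protocol's own: 23
participants × 4 gestures × 10 repetitions (920 four-second trials) for
the offline comparison, and 20 training plus 20 replayed repetitions per
gesture for the single-user streaming scenario (the canonical user —
default profiles, effort variability active: a single-user test should
exercise the pipeline, not the luck of one random profile draw). The full
acceptance script completes in about a minute on one CPU.

## Known limitations

- Default gesture profiles and their overlap structure are conventions;
  absolute accuracy figures on synthetic data say nothing about accuracy
  on physiological recordings (the relative behaviour — classifier
  ordering, confusion structure, noise monotonicity — is what the tests
  pin down).
- The streaming emulation replays pre-recorded trials; it does not model
  actuation feedback, user adaptation, or electrode shift during wear.
- The band-pass clamping rule means that at fs = 200 Hz the pipeline
  filters 20–90 Hz; recordings sampled at ≥ 1 kHz use the full 20–450 Hz
  band unchanged.
- Model persistence uses joblib pickles, which are Python/scikit-learn
  version-bound; the format version field guards against silent drift.
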