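# Methods

## Scope and model

`fallsense` implements an offline training-and-evaluation pipeline for
pre-impact fall detection from a single waist-worn 6-axis IMU at 100 Hz,
plus the streaming-order primitives (causal filtering, continuous attitude
state, forward rolling windows) needed to evaluate deployment behavior.

The central modeling idea is *dual-frame* feature extraction: the same
inertial signals are presented to the classifier both in the sensor body
frame and in a gravity-aligned global frame obtained from Madgwick attitude
estimation.  Global-frame signals make the vertical kinematics of a fall
(sinking of the center of mass, partial free fall) invariant to how the
sensor is worn; body-frame signals retain fine limb dynamics.  Four
independent branches (body/global × accel/gyro) are fused late by
concatenation.

## Attitude estimation

Hamilton quaternions, scalar-first.  Per sample: gyroscope prediction
`q̇_ω = ½ q ⊗ [0, ω_rad]`; if ‖a‖ > ε = 0.1 g, a normalized
gradient-descent correction toward the measured gravity direction with
gain β (default 0.1); first-order Euler integration at Δt = 1/fs and
renormalization.  Numerical choices:

* Gyroscope data are stored in deg/s and converted per step; accelerometer
  data in g, so the free-fall gate is a plain threshold on ‖a‖.
* The gradient norm is floored at 1e-12; a vanishing gradient (predicted
  and measured gravity already coincide) falls back to the gyro-only
  update and is logged at debug level.
* β = 0 is allowed and yields exactly pure gyroscope integration — the
  oracle used in tests.
* The filter state is re-initialized to identity at the start of every
  offline trial, and runs continuously from the recording start during
  rolling inference.
* Sign convention: at rest the accelerometer reads +1 g along the body
  axis anti-parallel to gravity; the global gravity reference is [0,0,1].

Without a magnetometer, yaw is unobservable from identity initialization:
the global frame's heading is anchored to the initial sensor orientation.
Consequently only gravity-referenced (roll/pitch) quantities are
orientation-invariant, and the tests assert invariance of the vertical
global-acceleration trace across wearing offsets that differ in roll and
pitch; horizontal-component alignment across yaw offsets is not asserted.

Warm-up convergence is measured as the earliest time the global
acceleration stays within 5° of vertical for 0.5 s.  From static tilts up
to 90° with β = 0.1 this occurs within ~8–10 s (the correction rotates the
estimate at ≈2β rad/s), comfortably under the 15 s bound asserted in tests.

## Preprocessing

Order per trial: truncate (falls only, at impact − 250 ms) → causal
4th-order Butterworth low-pass at 8 Hz on all six channels → Madgwick
transform over the whole truncated trial → windowing.  Causal single-pass
filtering (not zero-phase filtfilt) is used deliberately for parity with
streaming deployment.  Windows are 87 samples (⌊875 ms · fs / 1000⌋) with
stride 34 (⌊87 · 0.4⌋); fall trials are windowed in reverse from the
cutoff, ADL trials forward from the start; indexing is 0-based half-open.
Fall trials whose truncated length is under one window are excluded with a
logged reason.

**Window labels.**  A window is labeled fall when its overlap with the
annotated fall phase (onset → cutoff) reaches 0.5.  The overlap ratio is
normalized by `min(window length, fall-phase length)`: after 250 ms
pre-impact truncation the surviving fall phase of a sub-second fall is
5–35 samples — always shorter than the 87-sample window — so normalizing
by window length alone would label *no* window positive and contradict the
premise that fall windows exist and are augmented.  With the chosen
normalization the cutoff-anchored window (which contains the entire
surviving phase) always scores 1, and earlier windows drop off quickly.
The threshold comparison is inclusive.

## Augmentation

Training folds only, fall windows only, originals retained; each of the 7
copies applies jitter (σ = 0.04), scaling (one N(1.0, 0.10) factor per
window; 0.10 is interpreted as standard deviation), then time warping
(cubic-spline speed curve over 4 interior knots with N(1, 0.15²) knot
magnitudes, cumulative-integrated, endpoints fixed, speeds floored at 0.05
to keep the warp monotone).  The warp and scale are shared across a
window's four streams to preserve body/global timing consistency; jitter
is independent per stream and channel.  A composed transform per copy is
used because three single-transform variants cannot naturally produce
seven equal-sized copies.  The augmenter refuses datasets flagged as test
splits (structural leakage guard).

## Network

Per branch: DS-SE(3→16, k=9) → max-pool(kernel 2, stride 2; 87→43 with
floor) → DS-SE(16→32, k=7) → two causal temporal blocks (k=3, dilations 1
and 2; two depthwise-separable convolutions each, left-padded by (k−1)·d,
batch norm + SiLU + dropout 0.08, identity residual, output SiLU) → group
norm (4 groups over 32 channels) → global average pool → 32 features.
Heads: concat(4 × 32) → 128→48 linear + batch norm + SiLU + dropout 0.30 →
48→2 → softmax.

Design choices where the architecture was genuinely open:

* **Bias-free convolutions** everywhere (depthwise, pointwise): the
  separable parameter count is then exactly `C_in·k + C_in·C_out`, the
  compression ratios against standard convolutions are 5.76 and 5.74 for
  the two blocks, and the total of 30,522 trainable scalars serializes to
  59.61 KB in FP16.
* **SE blocks** use hidden width ⌊C/6⌋ (floored at 1), ReLU inner, sigmoid
  outer, applied to post-BN/SiLU features; the two small SE linear layers
  carry biases (the standard SE form; toggleable via `ModelSpec.se_bias`).
* **Group norm groups** = 4 (divides 32, keeps 8 channels per group).
* Max pooling uses floor semantics for odd lengths (87 → 43).
* Two-branch ablation variants ("body", "global") reuse the identical
  branch structure with a 64-wide fused layer.

The implementation is a purpose-built numpy layer framework
(`fallsense.nn`) with hand-derived backward passes for every layer
(separable convs, batch/group norm, SE, pooling, dropout, residual
blocks), verified against central finite differences (rel. tol 2e-4) on
the full composite network.  Training runs in float32 for throughput;
gradient-verification tests use float64.

## Training recipe

AdamW (lr 1e-3, decoupled weight decay 8e-5, applied to all parameters),
cosine annealing with warm restarts stepped per epoch (T0 = 15, T_mult =
2, η_min = 1e-6, restarts at epochs 15 and 45), class-weighted
(inverse-frequency, normalized to mean 1) cross-entropy with label
smoothing 0.01, batch 64, gradient clipping at global ℓ2 norm 0.8, default
105 epochs, seed 42 for initialization, shuffling and dropout.  No early
stopping or validation-based selection: the final-epoch model is evaluated
once per fold.  Cross-validation is grouped by subject (sklearn
GroupKFold); a runtime guard raises if any subject appears on both sides
of a fold.

## Evaluation

Window metrics use decision `p ≥ 0.5`.  Trial-level max-voting takes the
maximum window probability with an *inclusive* threshold (score not lower
than 0.5 ⇒ fall); rolling-inference alarms use a *strict* threshold
(probability exceeds 0.5) — both conventions kept deliberately as the
deployment rules they mirror.  The rolling alarm time is the wall-clock
time of the triggering window's final sample; inference latency is not
added.  Rolling inference never reads any sample at or after the impact
frame (the tests poison post-impact samples with NaN to prove it).  Lead
time is impact time minus alarm time; summary statistics (detection rate,
median/mean lead, compliance at 100/150/200/250 ms, ECDF) are computed
over detected trials, with misses counted in the detection rate only.

## Synthetic cohort

The generator builds each trial from a trunk orientation trajectory plus a
global-frame linear acceleration, renders sensor signals through a
per-subject constant wearing-offset rotation, and derives the gyroscope
stream from the exact orientation increments — so integrating the
generated gyro recovers the generating trajectory (the attitude module's
ground-truth oracle), and ‖a‖ ≈ 1 g whenever the linear acceleration is
small.  ADL kinds: static, walk (gait-frequency oscillation 1.6–2.4 Hz),
sit-stand cycles, small jumps (with a genuine flight-phase dip), and a
rapid sit-to-ground (abrupt trunk tilt with a partial free-fall dip whose
magnitudes overlap a fall's pre-impact phase — the rotational hard
negative).  Falls: 2–4 s of ordinary activity, then a 300–600 ms descent
in which the trunk rotates 60–85° toward horizontal while ‖a‖ dips to
0.2–0.45 g, the annotated impact, a >2 g spike placed *after* the impact
frame (truncation removes it; the classifier must use pre-impact dynamics
only), then quiet lying.

Default conditions, chosen once: 8 subjects × (4 ADL + 3 fall) trials,
ADL duration 10–30 s, wearing offsets uniform within ±35° per axis, noise
0.02 g / 1 deg/s (MEMS-grade at 100 Hz).  The orientation-stress preset
widens offsets to ±75° for the ablation comparison.  Randomness derives
from per-(seed, subject, trial) counter-keyed substreams, so datasets are
bit-reproducible and order-independent.

The orientation-stress preset (±75° offsets) makes two further
construction choices, both parts of the regime it is meant to emulate
rather than tuning knobs:

* **Warm-up before falls** (12–16 s of pre-fall activity): from a 75°
  offset the attitude filter converges at roughly 2β rad/s from identity
  initialization, i.e. in 7–8 s, and deployment prescribes a warm-up for
  the same reason.  Short-pre-fall trials under large offsets would feed
  the four-branch model unconverged attitude error in place of
  gravity-aligned signals.
* **Rotational hard negatives**: every subject's ADL mix includes the
  sit-to-ground kind, whose tilt rates (~80–230 deg/s peak) and dips
  (0.30–0.42 g) are placed inside the fall's visible pre-cutoff range.
  Without it the classes separate on rotation-invariant magnitude cues
  that any frame captures equally, and wearing orientation becomes
  irrelevant; with it the discriminating feature is the motion's direction
  relative to gravity — the quantity the coordinate transformation makes
  mount-invariant.

What the generator does **not** emulate: biomechanically validated fall
kinematics, near-fall recoveries (stumble-and-catch), soft-tissue or
mounting vibration, sensor bias drift and axis misalignment, and the
heavy-tailed activity diversity of real cohorts.  Passing the end-to-end
tests therefore demonstrates that the pipeline's machinery (transforms,
windowing, leakage-free training, voting) works and that the dual-frame
representation helps under wearing-orientation variation — not that the
reported synthetic metrics transfer to any real dataset.

## Problem sizes used in the test suite

The end-to-end acceptance tests run the full recipe for one complete
annealing cycle (15 epochs) rather than the 105-epoch default: the
synthetic classes are separable by construction and one cycle converges
(final fold losses ≈ 0.04).  The orientation ablation runs on a reduced
stress cohort (3 ADL + 2 falls per subject, ADLs 8–12 s) — the comparison
is directional (four-branch F1 ≥ body-only F1), not a headline metric.
With these sizes the two training tests take roughly 6 and 8 minutes
respectively on one CPU core.

## Known limitations

* No magnetometer fusion: heading is arbitrary, so yaw-dependent global
  components are only consistent within a trial, not across trials.
* The numpy training loop is single-threaded and ~2 orders of magnitude
  slower than a GPU framework; it is sized for reference-scale
  experiments, not large datasets.
* Non-100 Hz recordings are not resampled; `fs` is taken from the config.
* The deployment lockout state machine (alarm suppression after a
  trigger) is out of scope; rolling inference reports every trial's first
  alarm.
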