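# Methods

`gaitfusion` implements a two-stage hierarchical recognizer for eight daily
activities — standing, sitting, sit-to-stand, stand-to-sit, level walking,
running, stair ascent, stair descent — from two synchronized wearable
modalities sampled at 100 Hz: a 12-channel plantar-pressure insole pair
(6 piezoresistive sensors per foot) and four lower-limb inertial nodes
reporting Euler angles (roll/pitch/yaw per thigh and shank). Because no
public recording of this sensor configuration exists, the package ships a
biomechanically parameterized signal simulator that is itself first-class,
tested code; every benchmark in the package runs on simulated subjects.
This note records the model, the defaults, and the design decisions taken
where the design was genuinely open.

## Signal model of the simulator

**Dynamic gaits.** Each foot follows a cyclic phase at the activity
cadence; one per-foot gait cycle lasts `1 / cadence` seconds, and the feet
are half a cycle out of phase. During the stance fraction *s* of the cycle
the six sensors of a foot emit smooth raised-cosine bursts whose centres
progress from heel (early stance) through arch and metatarsals to toe
(late stance), scaled by per-sensor weights and the activity's peak
pressure; outside stance the pressure is exactly zero before noise. A
smooth contact envelope with 8%-of-stance cosine ramps bounds every burst.
Thigh and shank roll oscillate sinusoidally at the cycle rate with the
left and right legs in anti-phase (the ~180° phase offset of alternating
gait); pitch oscillates at twice the cycle rate (loading + push-off); yaw
is a slow, low-amplitude wander, larger for stair ascent ("unstable yaw").

Two geometric facts drive the phase structure. For two equal stance arcs
on a cycle, the dual-support fraction (both feet grounded) is at least
`2s − 1`, attained at the half-cycle offset; with the default walking
stance fraction of 0.60 the nominal dual support is 0.20, and the contact
floor (below) trims the burst edges so the measured value lands inside the
documented 10–20% range (~17%). For running, `s = 0.38 < 0.5` produces
flight phases and an exactly zero dual-support fraction — the criterion
that separates running from walking.

Default per-activity parameters (peak-to-peak roll amplitudes in degrees):

| activity | cadence (steps/s) | stance | thigh roll | shank roll | pitch | peak kPa |
|---|---|---|---|---|---|---|
| walking | 1.0 | 0.60 | 100 | 100 | 10 | 400 |
| running | 2.2 | 0.38 | 100 | 100 | 12 | 600 |
| stair ascent | 1.35 | 0.62 | 60 | 70 | 25 | 420 |
| stair descent | 0.75 | 0.62 | 30 | 70 | 5 | 420 |

**Static postures.** Standing is constant heel-dominant loading
(55/50/15/35/30/20% of peak across heel-medial/heel-lateral/arch/
metatarsal-medial/metatarsal-lateral/toe); sitting is the same shape at
roughly one-tenth the level. Sitting places the thigh near horizontal
(pitch 80°).

**Transitions.** Sit-to-stand renders the centre-of-gravity transfer as an
early heel rise, a rapid heel drop with a simultaneous forefoot surge, and
heel restabilization at the standing level, over a configurable 2 s ramp.
Stand-to-sit is deliberately *not* the time-mirror: a heel overshoot above
standing level accompanies a rapid forefoot decay. This asymmetry matters:
almost all window statistics extracted downstream are invariant under time
reversal, so mirrored waveforms would make the two transitions genuinely
confusable; real sit-to-stand and stand-to-sit pressure profiles are
likewise morphologically distinct, which is what the recognizer exploits.
Uniform-label transition recordings tile a repetition cycle (short hold,
ramp, short hold, quick return blend), emulating a subject repeating the
action; inside continuous sessions a transition is a single ramp, so
sessions are continuous across segment boundaries.

**Noise.** Additive Gaussian, independent per channel: 5 kPa SD on
pressure (clipped at zero, preserving nonnegativity) and 1.5° on angles,
then wrapped to the sensor's (−180°, 180°] output interval. These floors
keep the peak-signal-to-noise ratio high (gait pressure bursts are
hundreds of kPa) while making every statistical feature noisy enough that
classification is nontrivial. What the simulator does **not** model: soft
tissue dynamics, ground-reaction-force physics, sensor hysteresis and
drift, inter-cycle variability within a subject (cycles are exactly
periodic up to noise), gait pathologies, and left/right asymmetries in
transitions. Passing benchmarks therefore demonstrate pipeline
correctness and internal consistency, not field performance on human
subjects.

**Sensing chain.** The transduction arithmetic is modelled explicitly:
sensing area of the 7.5 mm circular zone (4.418 × 10⁻⁵ m²), force/area →
kPa (100 N ≈ 2263.5 kPa ceiling, comfortably above the ~800 kPa
physiological peak), a monotone decreasing piezoresistive characteristic
`R(F) = c/(F + ε)` with unloaded resistance above 10 MΩ (the figure-level
characteristic is not tabulated anywhere, so `c` and `ε` are exposed
configuration), and a 20 kΩ DC voltage divider at 3.3 V. Sensor
coordinates (2 heel, 1 arch, 2 metatarsal, 1 toe per foot, in mm) are a
stated convention, configurable through `SensorLayout`.

## Preprocessing

- **Kalman update** — the generic linear predict/correct step (the
  primitive inside 9-axis orientation fusion firmware). The simulator
  emits Euler angles directly, so the operation is a standalone primitive
  validated against hand matrix arithmetic, not part of the synthesis path.
- **Unwrapping** — the ±360° cycle-counter recursion; exactly invertible
  by construction (the corrected angle is `raw + 360k` with integer `k`).
- **Savitzky–Golay smoothing** — local least-squares polynomial fit,
  solved from the normal equations `(AᵀA)a = AᵀX` on the centered window;
  defaults m = 5, k = 3 (no values are prescribed anywhere, these are
  conventional for 100 Hz gait data). Boundary points are refit on the
  truncated window at the point's own offset, with the degree reduced only
  if fewer samples than coefficients remain. Smoothed pressure is clipped
  at zero.
- **Windowing** — 128 samples (1.28 s) stepped by 32 (75% overlap); the
  window label is the majority frame label, ties resolved toward the label
  seen earliest in the window.

## Features

Per pressure channel, 15 time-domain statistics and 3 spectral values;
12 channels plus 6 global biomechanical features give 222 dimensions. Per
angle channel, 14 time-domain and 10 spectral values; 4 nodes × 3 angles
give 288. Fused: 510 exactly. The documented 12 time statistics (max,
min, mean, RMS, absolute mean, variance, SD, peak-to-peak, IQR, skewness,
kurtosis, zero-crossing rate) are padded to the stated count of 14 with
signal energy (mean square) and crest factor; pressure channels add the
contact ratio as the 15th. Zero-crossing rate is computed on the
mean-removed signal; higher moments of a near-constant window are reported
as zero rather than amplified numerical noise.

Spectra use a Hanning taper zero-padded to N = 512 (bin width
100/512 ≈ 0.195 Hz); all band-limited quantities live in the 0.5–20 Hz
physiological gait band. Spectral prominence — the source material labels
the equation but prints only the centre-of-pressure formulas — is defined
here as peak amplitude over mean in-band amplitude (≥ 1, exactly 1 for a
flat spectrum). Band-energy ratios partition the in-band power into
0.5–3, 3–8 and 8–20 Hz (a configurable convention). Spectral centroid and
bandwidth are power-weighted; the amplitude SD and the bandwidth are
genuine standard deviations (square roots), as their names require.

The centre of pressure is the pressure-weighted centroid over all 12
sensor coordinates; frames whose total pressure falls below the contact
floor (5% of peak) are flagged undefined (NaN), never fabricated. The six
global features are mean COP-X, mean COP-Y, COP path length over defined
frames, dual-support ratio, stance ratio, and the left/right load-symmetry
index `(L − R)/(L + R)` (0 for symmetric loading). The optional add-ons
(4 roll ranges of motion + the zero-lag left/right thigh-roll
cross-correlation) are excluded from the default fused vector because
222 + 288 = 510 exactly; enabling them yields 515.

## Stage-1 routing

A window first passes a time-domain energy gate: the sum over channels of
the mean squared deviation from each channel's window mean. Detrending is
deliberate — constant standing load would otherwise register as enormous
"energy" and defeat the static gate. Below `T_E` the window is static and
**no spectral computation happens at all** (the compute-saving path,
asserted by a call-count test).

Windows above the gate are tested for periodicity. The significance
statistic is the in-band spectral prominence of the **left-minus-right**
foot-total pressure. The obvious alternative — prominence of the summed
pressure — fails: at a 1.28 s window, a single sit-to-stand transfer wave
is spectrally *more* concentrated (one smooth pulse → one narrow
low-frequency lobe, prominence 9–30 on simulated data) than periodic gait
(energy spread across harmonics, prominence 4–7), which would invert the
routing. The differential signal instead encodes the defining property of
locomotion: the feet alternate, so walking/running/stairs produce a strong
periodic differential, while posture transfers load and unload both feet
together and leave the differential noise-like. Measured on simulator
defaults, static and transition windows score ≤ 5.2 and dynamic windows
≥ 8.5.

Defaults, calibrated once on the simulator's default conditions and fixed
in the configuration: `T_E = 2000 kPa²` (static postures measure ≲ 70,
locomotion ≳ 10⁵), `T_Ratio = 6.5` (the midpoint of the measured gap).
Both are mandatory configuration keys. There is no hysteresis across
windows; temporal smoothing is the static branch's FSM's job.

## Static branch

Pressure-only features (the leading 222 columns) feed a standardized
RBF-kernel SVM with per-class scores, tuned by a small grid search. A
four-state finite state machine then rejects physically impossible
posture successions: each state may persist or advance one step along
sitting → sit-to-stand → standing → stand-to-sit → sitting. An illegal
prediction is replaced by the held current state — "reject", not "repair",
which also means a legal prediction is never altered. Aborted transitions
(sit-to-stand → sitting) are illegal by default; the transition table is
plain data and user-editable. The initial state is the first raw
prediction. The FSM restarts at each contiguous run of static-routed
windows (a dynamic interruption resets it).

## Dynamic branch

Base learners: a random forest and a gradient-boosted tree ensemble
(`HistGradientBoostingClassifier`) on the handcrafted features, plus an
optional dual-branch 1D CNN on the raw 12×128 blocks. The network — two
convolutional blocks per branch (conv, batch norm, ReLU, max pool), global
average pooling, concatenation, one fully connected softmax layer with
dropout 0.4, Adam at 10⁻³, batch 64, early stopping with patience 10 and
an epoch cap of 100 — is implemented directly in numpy (im2col
convolutions with analytic backprop, verified against finite differences),
so the package has no deep-learning framework dependency; kernel size 5,
16 filters and pool 2 are configuration defaults.

Calibration, fitted on a held-out 20% stratified calibration split:
per-class sigmoid (Platt) scaling of the GBDT's decision scores; the
forest's native averaged vote (identity); single-parameter temperature
scaling of the network's logits (a monotone transform, so the top-class
ranking is preserved). Vote weights are accuracy-proportional on the
calibration split (equal weights selectable) and always form a convex
combination, so the soft vote returns a probability vector and preserves
any unanimous argmax. Ties break toward the fixed (sorted) class order.

## Evaluation protocol

Leave-one-subject-out: one fold per subject, the full pipeline (router +
both branches) retrained on the remainder, fold assignment strictly by
subject. Reported statistics are the per-subject accuracy mean, sample SD
(n − 1), and the t-based 95% CI `mean ± t(n−1, 0.975)·SD/√n` — this CI
convention exactly reproduces the published six-subject reference
statistics (96.17 / 2.48 / [93.57, 98.77]), which is why it was adopted.
The pooled 8-class confusion matrix is reported with both recall and
precision per class.

Modality ablations mask feature columns and retrain. The IMU-only
configuration cannot run the pressure-based router; its documented
fallback routes every window to the dynamic branch, trained with the four
static classes folded in as extra classes. The PCA ablation fits the
reduction on training folds only (constant columns dropped first),
retaining components for 95% of variance.

**Benchmark population and scale.** Six simulated subjects with ±10%
multiplicative jitter on cadence, amplitudes and peak pressure. Static and
transitional data are continuous labeled sessions (repetitions of sitting
→ sit-to-stand → standing → stand-to-sit) so transition windows carry true
per-frame labels; each dynamic gait is a separate recording. The package's
standard benchmark uses 3 session repetitions with 3 s holds and 18 s per
dynamic gait with single-point tuning grids — a deliberate scale choice
for a single-CPU benchmark; the generator accepts larger durations and
grids unchanged. At this scale the fused pipeline reaches ≈ 99.9% LOOCV
accuracy, pressure-only ≈ 93.8% and IMU-only ≈ 94.3% (fused dominates
both, the expected ordering) — figures recomputed by the test suite, and
statements about simulated data only.

## Numerical choices and degenerate inputs

- Silent (all-zero) spectra degenerate to main frequency = band floor,
  centroid 0, prominence 1; band-energy ratios 0.
- Undefined COP frames are NaN; windows with no defined frame report zero
  COP features. A zero-variance thigh-roll pair makes the add-on
  cross-correlation undefined (NaN from the primitive, 0 in assembled
  vectors, which must be finite).
- The Kalman correct step rejects a numerically singular innovation
  covariance (condition number > 10¹⁴).
- Crest factor of an all-zero window is 0; contact ratio of an unloaded
  window is 0.
- All randomness flows from explicit integer seeds; identical seeds give
  bit-identical recordings, fits and predictions.

## Known limitations

- The simulator's perfect periodicity and symmetric transitions make the
  benchmark easier than human data; published human-subject accuracies are
  expressly not claimed.
- The stage-1 defaults are calibrated to the simulator's amplitude scale;
  real deployments must recalibrate `T_E` (units kPa²) to their sensors.
- The differential-pressure significance statistic assumes bilateral
  sensing; a single-insole deployment would need the (weaker) summed-signal
  variant plus a transient rejector.
- The numpy CNN is single-threaded and meant for small training sets; it
  is the ensemble's optional third voice, not a performance showcase.
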