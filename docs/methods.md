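# Methods

This note documents the models, numerical choices and open design decisions
behind `claudigait`, and what the synthetic validation does and does not
establish about real data.

## Resampling and filtering

Phone OSes deliver inertial samples irregularly (power saving, event
batching). Each sensor channel is linearly interpolated onto one shared grid
`t0 + k/50` s covering the observed span; extrapolation beyond the span is
forbidden (it would invent data), duplicate timestamps keep the last sample,
and timestamps are auto-detected as milliseconds when the median raw spacing
exceeds 1. Channels are then filtered with a 4th-order Butterworth low-pass
at 5 Hz applied forward–backward. Zero-phase filtering is a deliberate
choice: the filter is applied twice (amplitude response |H|²), which steepens
the roll-off slightly, but it introduces no group delay, so gait-event times
are not shifted — essential because stance/swing times are read off filtered
extrema. All later stages assume this order: filter the channels first, then
derive magnitudes.

## Walking detection

A sample counts as walking when the centered 1 s rolling standard deviation
of the acceleration-magnitude series is ≥ 1 m/s²; walking runs shorter than
2 s are relabeled rest. The 1 m/s² threshold is applied to the magnitude of
the *measured* (gravity-included) acceleration, which is invariant to phone
orientation. The window length (1 s spans at least one step at any plausible
cadence) and the 2 s minimum run are this package's choices; only the
threshold itself is an externally fixed study condition.

## Orientation estimation

The Madgwick MARG complementary filter propagates the quaternion by gyro
integration and corrects it along the normalized gradient of the squared
error between measured and predicted gravity/magnetic-field directions. The
implementation works directly in the package's Earth frame (Y up, magnetic
north = +Z horizontal component): the correction Jacobian is derived for an
arbitrary Earth-frame reference vector, and the magnetic reference is
re-computed each step from the measured field rotated into the Earth frame
and flattened to (0, h_y, √(h_x²+h_z²)) — so only the horizontal field
direction constrains yaw, and field-inclination errors cannot leak into
roll/pitch. Defaults: gain β = 0.1 (standard MARG range: large enough to
bound gyro drift, small enough not to chase motion acceleration) and a 5 s
warm-up excluded from gait analysis. The filter is initialized TRIAD-style
from the first accelerometer/magnetometer sample, so the warm-up absorbs
noise settling rather than large-angle convergence. Samples with zero-norm
accelerometer or magnetometer readings fall back to gyro-only integration
for that step; without any magnetometer the IMU-only variant runs and yaw is
flagged unreferenced.

Euler angles follow the smartphone convention — roll about the device Z
axis, pitch about X, yaw about Y, composed intrinsically as
R = R_Y(yaw)·R_X(pitch)·R_Z(roll). Segment medians of yaw are computed
circularly (unwrapped about the circular mean) because ±180° is one
direction, not two. Magnetic declination is ignored: only relative
orientation matters downstream. Gravity is removed after rotation by
subtracting the constant (0, 9.8, 0) m/s²; the switch is exposed
(`fusion_remove_gravity`) because the spectral features otherwise carry a
large DC term.

## SSA gait-event detection

Each window's vertical (Y) and anterior–posterior (Z) Earth-frame channels
are decomposed by singular spectrum analysis: Hankel trajectory matrix with
embedding length L = 2 s of samples (100 at 50 Hz; long enough to hold more
than one stride at any cadence in the supported range), SVD, and
reconstruction of every elementary component by diagonal averaging
(implemented as a convolution of the singular vectors divided by diagonal
lengths, which makes the components an exact additive partition of the
input). Trend is the set of components whose periodogram peak lies below
0.5 Hz — sub-gait content such as posture drift; taking *all* such components
rather than only a leading run means a slow drift cannot hide behind a
stronger oscillation. The *dominant oscillation* is reconstructed from the
leading eigen-group: component 0 plus component 1 when their singular values
are within a 0.7 ratio. A pure oscillation occupies a quadrature *pair* of
near-equal singular values; reconstructing from one member alone would
return an arbitrary-phase sinusoid, while the pair is phase-faithful to the
input — the property event timing depends on.

Detection then proceeds: (1) order-based local minima of the dominant Y
oscillation (order = 25 % of the estimated step period, suppressing
micro-extrema) give one candidate interval per step; (2) within ±25 % of the
median inter-minimum spacing around each minimum — wide enough to correct
the smooth oscillation's phase error, narrow enough never to reach a
neighboring contact — the sample minimizing y·z is the heel contact; (3)
parity is decided once from the first three dominant-oscillation minima (if
the mean of the detrended Y signal over the first inter-minimum span exceeds
the mean over the second, the first contact is a right heel contact) and then
alternates; "mean amplitude" is read as the plain mean of the detrended
signal, the most literal reading; (4) the right toe-off is the first local
minimum of detrended Y strictly after a left heel contact (before the next
right contact), the left toe-off the last local maximum before it. Cycles
run between consecutive right heel contacts; cycles without a qualifying
toe-off keep their stride time but contribute no stance/swing statistics.
Left/right labels are phone-side-relative — the pocket side produces the
larger ipsilateral signal and the parity rule keys on exactly that
asymmetry — so no anatomical left/right is claimed.

SSA runs per 10 s window (matching the windowed feature pipeline); whole-walk
operation is available by calling the detector on a full recording, as the
validation tests do.

## Features

70 time-domain values per window: max/min/mean/median/sample-std (N−1
denominator) of ‖a‖ and the three components; 10-bin histograms of each
signal over the window's own [min, max] with frequencies rather than counts
(per-window ranges keep the feature amplitude-invariant, frequencies keep it
length-invariant; a global range is undefined without a reference
population); per-axis RMS ratios (their squares sum to 1 by construction);
signal magnitude area; non-excess kurtosis m₄/m₂²; skewness m₃/m₂^{3/2};
LCSS similarity between consecutive gait-cycle segments of ‖a‖ (two samples
match when they differ by ≤ ε = 0.5·std(‖a‖) and their index offset is
≤ 10 % of the shorter cycle; length-normalized by the shorter cycle);
cadence; mean stride time; and the swing/stance ratio. The swing/stance
feature is implemented as the *stance percentage* of the gait cycle, whose
classical normal value is ~60 %; a `swing_minus_stance` mode (≈ −20 points
for normal gait) is provided because the name admits either reading.

85 frequency-domain values, all from ‖a‖ with the window mean removed first
so the excluded-DC convention is exact: Welch PSD max/mean/min (Hann window,
128-sample segments, 50 % overlap — fixed here, exposed in config);
normalized spectral entropy of FFT magnitudes over positive non-DC bins
(−Σp ln p / ln M ∈ [0, 1]); spectral energy Σ|X_k|²/N (equal to Σx² by
Parseval); 40 FFT magnitudes scaled by 2/N at bins 1–40 of the 500-sample
window (exactly 0.1–4.0 Hz at 0.1 Hz steps); and 40 orthonormal type-II DCT
coefficients at bins 2, 4, …, 80 — the even bins are the only selection that
honors the 0.1 Hz spacing, since DCT bin k sits at k·fs/(2N) = 0.05·k Hz.

Features undefined on a window (zero variance, fewer than two cycles, no
toe-off) carry NaN; dataset assembly either drops such rows (default) or
imputes column medians, and windows with zero detected cycles are always
dropped and counted.

## Windowing and labels

Windows are 10 s with 50 % overlap, anchored inside each walking segment (so
rest periods create no phantom windows); a rest-free duration-D walking
record yields ⌊(D−10)/5⌋+1 windows. A window is labeled claudication-positive
when at least half of it lies at or after the reported pain onset —
equivalently, when its midpoint does; the symmetric choice among defensible
window-level rules, switchable to start-after-onset. Labels are therefore
monotone in time within a walk.

## Classification

The registry fixes one hyperparameter set per model (300 trees / depth-6
boosters at learning rate 0.1 for the boosted models, 300-tree forests,
100-stage classic gradient boosting) rather than running automated
hyperparameter search: reproducibility over opaque tuning. Record-wise
splits are stratified by label; patient-wise splits assign whole patients
greedily (best-first) toward a 20 % test fraction. Cross-validation is
stratified K-fold record-wise and grouped K-fold patient-wise — grouping the
folds by patient is the safer reading and is switchable (`group_cv`).
Probability threshold 0.5; AUC from positive-class probabilities
(trapezoidal); leakage (a patient on both sides of any fold or split) is
asserted on every run.

## Synthetic data generator

The generator emulates the target protocol: ~6-minute walks at self-selected
speed, phone free-oriented in a trouser pocket, a reported pain-onset time,
per-patient idiosyncrasies, occasional rest blocks. Gait is a stride-phase
process (right heel contact at phase 0, left toe-off at c−0.5, left heel
contact at 0.5, right toe-off at the stance fraction c). The Earth-frame
vertical channel follows a band-limited per-stride template — a monotone
cubic through knots that place a deep pocket-side minimum at the right heel
contact, a maximum at the left toe-off, a steep descent through the left
heel contact into the right-toe-off minimum, and a mid-left-step recovery
maximum — plus a damped ~4.5 Hz impact transient at each right (pocket-side)
heel contact. The anterior–posterior channel peaks sharply at every heel
contact ((0.5+0.5cos 4πs)⁴ plus a phase-shifted stride-frequency term);
medio-lateral is low-amplitude sway. The asymmetries are purposeful: the
pocket-side impact and the positive/negative mid-step structure are what the
left/right parity rule and the toe-off extrema rules key on. Defaults
(stride 1.1 s ≈ 109 steps/min, stance 0.60, vertical amplitude 2.5 m/s²,
impact 3 m/s², noise 0.25 m/s² / 0.02 rad/s / 0.5 μT, 2 ms timestamp jitter)
are chosen as typical of moderately impaired walking recorded at the hip
pocket with phone-grade MEMS sensors.

Claudication is modeled as a change-point at the pain onset: stride time
lengthens by 1/cadence_factor, stride-time variability scales by
variability_factor, amplitudes by amp_factor. Cohorts draw per-patient
latent parameters once (shared across that patient's trials) and per-trial
onsets and pocket poses. The priors deliberately make the between-patient
spread of baselines (stride 1.1±0.15 s, amplitude 2.6±0.5 m/s²) comparable
to or larger than the within-patient onset shift (cadence factor 0.93±0.035,
amplitude factor 0.88±0.06): post-onset walking of one patient then overlaps
pre-onset walking of another, so absolute feature thresholds do not transfer
across patients. That latent structure is what makes patient-wise evaluation
measurably harder than record-wise evaluation — the generalization-gap
phenomenon the split comparison exists to expose — while record-wise splits
remain highly separable.

The Earth-frame signal (gravity added) is rotated into the body frame by the
phone orientation, which wobbles a few degrees at step frequency; the
gyroscope reports the exact angular rate of that orientation path (central
differences of the quaternion trajectory) plus noise, and the magnetometer
the rotated Earth field (0, −30, 25) μT plus noise. A companion
`simulate_pose_sequence` produces the stationary two-pose recordings used to
validate the rotation stage (yaw 0°→180°; roll +90°→−90°).

**What passing these tests does not show.** The simulator's waveform is a
stylized template, not forward dynamics: real pocket signals contain
soft-tissue and clothing artifacts, turns, asymmetric pathology-specific
waveform changes and magnetic disturbance, none of which are modeled. Event
recovery and classification results on simulated cohorts validate the
*implementation* (the algorithms recover the structure they are designed
for, splits are hygienic, effects propagate end to end) — they do not
certify clinical accuracy on real patients, which requires the real
recordings.

## Validation problem sizes

The packaged validation uses desk-scale problems: 40–150 s walks, 20-walk
stride sweeps (0.9–1.4 s), and a 16-patient × 2-trial × 150 s cohort
(~500 windows) for the split experiments; the acceptance script uses two 60 s
pose tests and one 120 s walk. These sizes give stable statistics for every
asserted tolerance while keeping the default runs fast.

## Known limitations

- Left/right event labels are phone-side-relative; anatomical sides require
  knowing the pocket side.
- The stance-fraction readout degrades toward the edges of the supported
  stance range (detection is validated for c ∈ [0.54, 0.68]).
- Yaw is referenced to magnetic north without declination correction.
- The rolling-std window for walking detection and the SSA embedding length
  are package choices; both are configurable but not externally prescribed.
- Real-time/streaming operation is out of scope; the pipeline is offline.
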