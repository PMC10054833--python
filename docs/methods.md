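# Methods

## The measurement problem

Levodopa relieves Parkinsonian motor symptoms for a few hours per dose;
between doses tremor and bradykinesia return, and at peak dose many patients
show dyskinesia instead. A home assessment system that records standardized
MDS-UPDRS-style movement tasks with sensor gloves can, in principle, read
the medication state directly from movement signals. `pdglove` implements
that full computational path and, because real patient sessions are not
publicly available, pairs it with a synthetic generator whose parameters
have explicit clinical meaning, so that every claim the package makes is
checked against known ground truth.

## Symptom and signal model (`synth`)

A participant is described by severities in `[0, 1]` for tremor,
dyskinesia, and bradykinesia, a tremor frequency in 3–10 Hz, and three
medication-response parameters:

| parameter | meaning | default sampling |
|---|---|---|
| `tremor_severity` | attitude tremor amplitude, 2° per unit | U(0.2, 0.8) |
| `dyskinesia_severity` | 2–5 Hz band-noise amplitude, 3° per unit | U(0.2, 0.8) |
| `brady_severity` | amplitude decrement `d`, interval jitter and slowing | U(0.2, 0.8) |
| `tremor_freq_hz` | tremor oscillation frequency | U(4, 8) |
| `med_tremor_suppression` | post-intake tremor attenuation | U(0.4, 0.9) |
| `med_brady_suppression` | post-intake decrement attenuation | U(0.4, 0.9) |
| `med_dyskinesia_gain` | post-intake dyskinesia scale (pre-intake it is 0) | U(0.5, 1.5) |

The default severity range emulates a mild-to-moderate cohort, which is the
population such feasibility systems target.

Kinetic tasks (finger tap FT, open–close OC, hand flip HF, finger-to-nose
FN) are trains of `K = 10` raised-cosine pulses on the task's primary
channel (flexion for FT/OC, roll for HF, pitch for FN) with amplitudes
`A_k = A_0 (1 − d·k/K)`; `d` is the bradykinetic decrement, attenuated
post-medication. Raised cosines are smooth, band-limited (negligible energy
above ~5 Hz at the default pulse widths, keeping the tremor band clean in
asymptomatic signals), and peak-detectable. Inter-pulse intervals slow by
`1 + 0.3 d` and jitter with σ proportional to the effective bradykinesia;
intervals are floored so pulses never overlap. Two seconds of rest precede
and three seconds follow the train, because participants receive the prompt
before moving and often finish early. Stationary tasks (hands out HH,
resting hands RH) hold a constant posture for exactly 10 s.

Tremor is a random-phase sinusoid on pitch and roll with a weak (0.04 V/°)
leak into the flexion channels; dyskinesia is unit-variance Gaussian noise
band-passed to 2–5 Hz (4th-order Butterworth, forward–backward filtered,
transients trimmed) — a deliberately agnostic waveform that matches the
feature band without asserting a specific movement pattern, and present
only post-medication, as a levodopa side effect. Accelerometer channels are
the gravity projection of the attitude trajectory (in g), gyroscope
channels its time derivative (deg/s), mirroring a device that computes
attitude on board; white noise is added per channel group (0.15° attitude,
0.01 V flexion, 0.005 g accel, 0.3 °/s gyro at `noise_scale = 1`), and
12-bit flexion quantization is available. Transport loss drops whole
32-sample blocks, aligned to the stream start, with the configured
probability — the default session loss rate of 0.345 puts the surviving
effective rate in the mid-80 Hz range against the 128 Hz source rate,
matching the regime a congested wireless link produces.

What the generator does **not** emulate: biomechanically coupled joint
kinematics, postural drift, sensor bias/scale error, task mis-performance,
or day-to-day symptom fluctuation beyond the pre/post contrast. Passing
tests therefore demonstrate that the pipeline recovers what the model puts
in — correctness of the machinery, not clinical validity on real patients.

## Transport dialect (`codec`)

The payload grammar (values as shortest round-tripping single-precision
decimals, semicolon-terminated, channel-major over a fixed 11-channel
order, 352 fields) is this package's own dialect: the upstream protocol
fixes only the delimiter, the 32-sample batching, and the hand/task topic
routing. Fixed order and count make the stream self-describing without
headers. Timestamps are assigned at ingest — 32 samples spaced at the
nominal rate, ending at the arrival time — never carried on the wire, and a
trailing partial payload at session end is never transmitted.

## Preprocessing

Resampling to 64 Hz uses linear interpolation onto the grid spanning
`[t_first, t_last]`. No anti-alias filter precedes it: all content of
interest lies below 10 Hz, well under the 32 Hz Nyquist limit. Attitude
reconstruction uses a complementary filter (gyro integration corrected
toward the accelerometer gravity angles, blend 0.98) rather than a full
AHRS because the hardware class modeled here has no magnetometer; yaw is
not estimated. Zero-norm accelerometer samples carry the previous
correction angle.

## Activity windowing

Frame energy is the per-frame variance (mean-removed within the frame), so
constant offsets carry no energy and boundaries are invariant to gain and
offset (energies and threshold both scale by the square of the gain). The
threshold is `T = E_min + α (E_mean − E_min)` with `E_min` floored at
1e-12 to survive exactly-silent recordings. Active runs whose *uncovered*
time gap (frame overlap accounted for) is shorter than `merge_gap` are
merged; sub-`min_seg` segments are dropped; the highest-total-energy
segment is the primary window. Defaults — frame 0.25 s, hop 0.125 s,
α 0.3, min segment 0.5 s, merge gap 0.5 s — are sized so tap trains at
1–3 Hz do not fragment. Stationary tasks bypass the detector and are used
whole: their duration is protocol-fixed, and windowing them would discard
exactly the sustained posture the features target.

## Features

The periodogram is a single mean-removed rectangular-window FFT per
(sub)segment, normalized so bin powers sum to the total mean-removed power;
segments of 2–10 s give ≥ 0.1 Hz resolution, ample for 2–10 Hz bands. Band
energy sums bins over `[lo, hi)`; a band ending exactly at Nyquist includes
the Nyquist bin so a disjoint partition of `[0, fs/2]` is exactly Parseval.
Tremor uses 5–10 Hz and dyskinesia 2–5 Hz — the bands with the strongest
published discriminative record for these symptoms; the generator exposes
`tremor_freq_hz` down to 3 Hz so the band choice itself can be stress-tested.

Peak detection requires prominence ≥ a quarter of the 5th–95th percentile
range (robust to tremor ripple riding on taps) and 0.2 s separation;
valleys are minima between consecutive peaks, and a peak's amplitude is its
height above the mean of its adjacent valleys. Kinetic windows are split
into three equal thirds (start/middle/end, earlier sections take the
remainder samples) to expose the bradykinetic sequence effect as
start-to-end amplitude and interval changes; stationary recordings are
split into halves, where late-segment spectral change is the signal of
interest. Empty peak series produce sentinel 0 features with the
`peak_count` feature recording the evidence, keeping vectors dense.
Feature ids follow `<task>_<hand>_<channel>_<section>_<stat>`; the third
flexion sensor is canonically labeled `middle` with aliases accepted, since
deployment documents disagree on the third instrumented finger.

The questionnaire bin-to-label mapping (0–3 h since intake → 0
"pre-medication", 4+ h → 1 "post-medication") follows the upstream
deployment's printed convention exactly. Pharmacologically it looks
inverted — levodopa's half-life is about 2.5 h, so 0–3 h since intake is
the medicated window — and an `invert` switch is provided; the default
remains as printed.

## Classification

Rows for the classifier are per-session: left- and right-glove features of
all tasks concatenated, with participant identifiers kept as metadata, never
as features. The 80–20 split is stratified by label and row-wise, which
mixes a participant's sessions across train and test — a deliberate mirror
of the upstream protocol, noted as an optimistic-bias source rather than
"fixed". Features are standardized on training statistics only. Model
hyperparameters are the scikit-learn defaults (MLP iteration cap raised to
800) and are recorded in the evaluation report.

Feature importance uses a permutation-sampling Shapley estimator written
for this package: for each sampled feature ordering, features switch one at
a time from a random background row (drawn from the test set) to the
explained row, and the change in the forest's class-1 probability is the
marginal contribution; 20 orderings over up to 100 test rows, aggregated as
mean |attribution| per feature. This is the classical Monte-Carlo Shapley
construction — unbiased in the number of orderings — and is independent of
any tree-internals shortcut.

A null-reference cohort (`simulate_null_table`) uses one session per
participant with zero medication response and a randomly drawn state label,
making labels exactly independent of features. Paired pre/post sessions
cannot serve as the null: with balanced labels within each participant, a
test row's nearest neighbors are dominated by the same participant's
opposite-label sessions, driving local models systematically *below*
chance — a real property of paired designs, not a pipeline leak.

## Problem sizes and determinism

The test suite and acceptance script run the generator at the study-like
default conditions (128 Hz source, 64 Hz analysis, 10-repetition tasks,
34.5 % loss where loss is under study). Windowing accuracy uses 100 seeded
finger-tap tasks; codec identity uses 1000 random payloads; classifier
sanity uses a 500-session null cohort and a 50-participant high-effect
cohort (severities ≥ 0.7, suppressions ≥ 0.8); end-to-end determinism
re-runs a 2-participant × 3-day pipeline twice and compares feature tables
byte for byte. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning, so identical configurations yield
identical artifacts.

## Known limitations

- Single-task effective-rate estimates under block loss are noisy (a 10 s
  window holds only 40 payload blocks, giving a ~10 Hz standard deviation);
  rate diagnostics therefore average across stationary windows and
  sessions.
- The classifier's perfect accuracy on default synthetic cohorts reflects
  the generator's strong, consistent medication effects; real cohorts show
  participant-specific, drifting effects the generator does not model.
- The wire codec assumes ASCII decimal payloads; no checksumming or
  reordering tolerance is implemented (transport is assumed in-order,
  lossy at payload granularity).
- Yaw and any heading-dependent feature are out of scope (6-DoF IMU).
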