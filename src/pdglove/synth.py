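"""Synthetic Parkinsonian glove-session generator.

Generates ground-truth-annotated two-glove sessions with the statistical
structure of Parkinsonian movement so every downstream stage — codec,
export, resampling, windowing, features, classification — is testable
without patient data.

Symptom model
-------------
* **Tremor**: a sinusoid at the participant's tremor frequency (3-10 Hz)
  superimposed on the attitude channels (and leaking weakly into flexion),
  with amplitude proportional to ``tremor_severity`` and attenuated after
  medication by ``med_tremor_suppression``.
* **Dyskinesia**: band-limited Gaussian noise filtered to 2-5 Hz, present
  only post-medication (a levodopa side effect), scaled by
  ``dyskinesia_severity * med_dyskinesia_gain``.
* **Bradykinesia**: in kinetic tasks the repetition train shows amplitude
  decrement ``A_k = A_0 * (1 - d * k / K)`` and inter-repetition jitter and
  slowing that grow with ``brady_severity``; medication attenuates ``d`` by
  ``med_brady_suppression``.

Repetitions are raised-cosine (Hann) pulses on the task's primary channel:
smooth, band-limited, and peak-detectable.  Accelerometer and gyroscope
channels are synthesized consistently with the attitude trajectory (gravity
projection and time derivative), mirroring a device that computes attitude
on board.  Transport loss is emulated by dropping whole payload-sized
blocks of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy.signal import butter, filtfilt

from pdglove.codec import PAYLOAD_SAMPLES, SensorFrame
from pdglove.tasks import (
    CHANNELS,
    DEFAULT_REPETITIONS,
    HANDS,
    KINETIC_TASKS,
    STATIONARY_DURATION_S,
    TASK_ORDER,
    validate_task,
)

#: Nominal glove sampling rate in Hz.
SOURCE_FS = 128.0

# Attitude-channel symptom amplitudes at unit severity (degrees).
TREMOR_ATTITUDE_AMP_DEG = 2.0
DYSKINESIA_ATTITUDE_AMP_DEG = 3.0
#: Fraction of an attitude-symptom amplitude leaking into flexion (V/deg).
FLEXION_LEAK = 0.04

# Per-channel white-noise standard deviations at noise_scale = 1.
NOISE_STD = {"attitude": 0.15, "flexion": 0.01, "accel": 0.005, "gyro": 0.3}

#: Flexion ADC reference voltage and 12-bit step.
ADC_VREF = 3.3
ADC_STEP = ADC_VREF / 4095.0

# (base inter-repetition interval s, pulse amplitude, baseline pitch/roll deg)
_KINETIC = {
    "FT": dict(interval=0.5, pitch0=0.0, roll0=0.0,
               pulses={"flex_index": 1.0, "flex_thumb": 0.3}),
    "OC": dict(interval=0.6, pitch0=0.0, roll0=0.0,
               pulses={"flex_index": 1.0, "flex_thumb": 0.8, "flex_middle": 0.9}),
    "HF": dict(interval=0.7, pitch0=0.0, roll0=0.0, pulses={"roll": 60.0}),
    "FN": dict(interval=1.0, pitch0=20.0, roll0=0.0, pulses={"pitch": 30.0}),
}
_STATIONARY = {
    "HH": dict(pitch0=5.0, roll0=0.0),
    "RH": dict(pitch0=10.0, roll0=45.0),
}
#: Resting flexion baseline (V).
FLEX_BASELINE = 0.5
#: Rest padding around the kinetic repetition train (s).
KINETIC_REST_PRE_S = 2.0
KINETIC_REST_POST_S = 3.0
#: Gap between consecutive tasks in a session (s).
TASK_GAP_S = 1.0


@dataclass(frozen=True)
class ParticipantProfile:
    """Simulator severity and medication-response parameters.

    Severities, suppressions, and the tremor frequency are bounded; a
    profile outside its declared ranges is rejected at construction.
    """

    participant_id: str
    tremor_severity: float = 0.0
    dyskinesia_severity: float = 0.0
    brady_severity: float = 0.0
    tremor_freq_hz: float = 5.0
    dominant_hand: str = "right"
    med_tremor_suppression: float = 0.0
    med_brady_suppression: float = 0.0
    med_dyskinesia_gain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tremor_severity", "dyskinesia_severity", "brady_severity",
                     "med_tremor_suppression", "med_brady_suppression"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 3.0 <= self.tremor_freq_hz <= 10.0:
            raise ValueError(f"tremor_freq_hz={self.tremor_freq_hz} outside [3, 10]")
        if self.med_dyskinesia_gain < 0:
            raise ValueError("med_dyskinesia_gain must be >= 0")
        if self.dominant_hand not in HANDS:
            raise ValueError(f"dominant_hand must be one of {HANDS}")


def random_profile(rng: np.random.Generator, participant_id: str,
                   severity_range: tuple[float, float] = (0.2, 0.8),
                   suppression_range: tuple[float, float] = (0.4, 0.9),
                   ) -> ParticipantProfile:
    """Draw a profile emulating a mild-to-moderate symptomatic participant."""
    lo, hi = severity_range
    slo, shi = suppression_range
    return ParticipantProfile(
        participant_id=participant_id,
        tremor_severity=rng.uniform(lo, hi),
        dyskinesia_severity=rng.uniform(lo, hi),
        brady_severity=rng.uniform(lo, hi),
        tremor_freq_hz=rng.uniform(4.0, 8.0),
        dominant_hand="right" if rng.random() < 0.9 else "left",
        med_tremor_suppression=rng.uniform(slo, shi),
        med_brady_suppression=rng.uniform(slo, shi),
        med_dyskinesia_gain=rng.uniform(0.5, 1.5),
    )


@dataclass
class TaskTruth:
    """Ground-truth annotations for one generated task signal."""

    task: str
    duration_s: float
    active_start_s: float
    active_end_s: float
    tap_times_s: np.ndarray   # empty for stationary tasks
    tap_amplitudes: np.ndarray
    tremor_amp: float
    dyskinesia_amp: float
    decrement: float


def _effective_params(profile: ParticipantProfile, med_state: str) -> tuple[float, float, float]:
    if med_state not in ("pre", "post"):
        raise ValueError(f"med_state must be 'pre' or 'post', got {med_state!r}")
    post = med_state == "post"
    tremor_amp = (TREMOR_ATTITUDE_AMP_DEG * profile.tremor_severity
                  * (1.0 - profile.med_tremor_suppression * post))
    dysk_amp = (DYSKINESIA_ATTITUDE_AMP_DEG * profile.dyskinesia_severity
                * profile.med_dyskinesia_gain * post)
    decrement = profile.brady_severity * (1.0 - profile.med_brady_suppression * post)
    return tremor_amp, dysk_amp, decrement


def _hann_pulse(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine pulse of the given width centered at ``center``."""
    u = (t - center) / width
    return np.where(np.abs(u) < 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * u)), 0.0)


def _bandlimited_noise(n: int, fs: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [lo, hi] Hz."""
    white = rng.standard_normal(n + 256)  # padding absorbs filter transients
    b, a = butter(4, [lo, hi], btype="band", fs=fs)
    x = filtfilt(b, a, white)[128:128 + n]
    std = x.std()
    return x / std if std > 0 else x


def generate_task_signal(task: str, profile: ParticipantProfile, med_state: str,
                         fs: float = SOURCE_FS,
                         seed: int | np.random.SeedSequence = 0,
                         repetitions: int = DEFAULT_REPETITIONS,
                         noise_scale: float = 1.0,
                         quantize_flexion: bool = False,
                         ) -> tuple[dict[str, np.ndarray], TaskTruth]:
    """Generate all 11 channels of one movement task at rate ``fs``.

    Kinetic tasks (FT, OC, HF, FN) contain a repetition train of
    ``repetitions`` raised-cosine events with bradykinetic amplitude
    decrement and interval jitter, padded by 2 s of rest before and 3 s
    after.  Stationary tasks (HH, RH) hold a posture for 10 s.  Output is
    deterministic under a fixed seed.
    """
    validate_task(task)
    if fs <= 2.0 * profile.tremor_freq_hz:
        raise ValueError(
            f"fs={fs} Hz must exceed twice the tremor frequency "
            f"({profile.tremor_freq_hz} Hz) to avoid aliasing")
    rng = np.random.default_rng(seed)
    tremor_amp, dysk_amp, decrement = _effective_params(profile, med_state)
    post = med_state == "post"
    jitter_brady = profile.brady_severity * (1.0 - profile.med_brady_suppression * post)

    kinetic = task in KINETIC_TASKS
    tap_times = np.empty(0)
    tap_amps = np.empty(0)
    if kinetic:
        cfg = _KINETIC[task]
        base_interval = cfg["interval"] * (1.0 + 0.3 * decrement)  # brady slows the train
        width = 0.7 * cfg["interval"]
        jitter_std = 0.12 * cfg["interval"] * jitter_brady
        centers = [KINETIC_REST_PRE_S + width / 2.0]
        for _ in range(repetitions - 1):
            step = base_interval + jitter_std * rng.standard_normal()
            centers.append(centers[-1] + max(step, width + 0.02))
        tap_times = np.asarray(centers)
        K = repetitions
        tap_amps = 1.0 - decrement * np.arange(K) / K  # relative amplitudes
        active_start = tap_times[0] - width / 2.0
        active_end = tap_times[-1] + width / 2.0
        duration = active_end + KINETIC_REST_POST_S
        pitch0, roll0 = cfg["pitch0"], cfg["roll0"]
    else:
        cfg = _STATIONARY[task]
        duration = STATIONARY_DURATION_S
        active_start, active_end = 0.0, duration
        pitch0, roll0 = cfg["pitch0"], cfg["roll0"]

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    pitch = np.full(n, float(pitch0))
    roll = np.full(n, float(roll0))
    flex = {name: np.full(n, FLEX_BASELINE) for name in
            ("flex_index", "flex_thumb", "flex_middle")}

    if kinetic:
        train = {}
        for ch, amp in cfg["pulses"].items():
            y = np.zeros(n)
            for center, rel in zip(tap_times, tap_amps):
                y += amp * rel * _hann_pulse(t, center, width)
            train[ch] = y
        for ch, y in train.items():
            if ch == "pitch":
                pitch += y
            elif ch == "roll":
                roll += y
            else:
                flex[ch] += y
        primary_amp = cfg["pulses"][next(iter(cfg["pulses"]))]
        tap_amps = tap_amps * primary_amp  # truth in primary-channel units

    # Tremor: sinusoid at the participant frequency, random phase per axis.
    if tremor_amp > 0:
        ph_p, ph_r = rng.uniform(0, 2 * np.pi, 2)
        trem_p = tremor_amp * np.sin(2 * np.pi * profile.tremor_freq_hz * t + ph_p)
        trem_r = tremor_amp * np.sin(2 * np.pi * profile.tremor_freq_hz * t + ph_r)
        pitch += trem_p
        roll += trem_r
        for name in flex:
            flex[name] += FLEXION_LEAK * trem_p
    # Dyskinesia: 2-5 Hz band-limited noise, post-medication only.
    if dysk_amp > 0:
        dy_p = dysk_amp * _bandlimited_noise(n, fs, 2.0, 5.0, rng)
        dy_r = dysk_amp * _bandlimited_noise(n, fs, 2.0, 5.0, rng)
        pitch += dy_p
        roll += dy_r
        for name in flex:
            flex[name] += FLEXION_LEAK * dy_p

    # Inertial channels follow the attitude: gravity projection (accel, g)
    # and time derivative (gyro, deg/s).
    pr, rr = np.radians(pitch), np.radians(roll)
    ax = -np.sin(pr)
    ay = np.sin(rr) * np.cos(pr)
    az = np.cos(rr) * np.cos(pr)
    gx = np.gradient(roll, 1.0 / fs)
    gy = np.gradient(pitch, 1.0 / fs)
    gz = np.zeros(n)

    channels = {"ax": ax, "ay": ay, "az": az, "gx": gx, "gy": gy, "gz": gz,
                "pitch": pitch, "roll": roll, **flex}
    if noise_scale > 0:
        for name in channels:
            group = ("attitude" if name in ("pitch", "roll")
                     else "flexion" if name.startswith("flex")
                     else "accel" if name in ("ax", "ay", "az") else "gyro")
            channels[name] = channels[name] + (
                noise_scale * NOISE_STD[group] * rng.standard_normal(n))
    if quantize_flexion:
        for name in ("flex_index", "flex_thumb", "flex_middle"):
            channels[name] = np.clip(np.round(channels[name] / ADC_STEP) * ADC_STEP,
                                     0.0, ADC_VREF)

    truth = TaskTruth(task=task, duration_s=n / fs, active_start_s=active_start,
                      active_end_s=active_end, tap_times_s=tap_times,
                      tap_amplitudes=tap_amps, tremor_amp=tremor_amp,
                      dyskinesia_amp=dysk_amp, decrement=decrement)
    return channels, truth


@dataclass
class SyntheticSession:
    """One generated two-glove session with ground truth.

    ``frames`` holds the surviving :class:`SensorFrame` stream per hand
    (after payload-block loss); ``task_boundaries`` maps hand -> task ->
    (start_us, end_us); ``truth`` maps (hand, task) to the generator's
    annotations, whose segment and tap times are relative to task start.
    """

    participant_id: str
    med_state: str
    fs: float
    session_datetime: str
    loss_rate: float
    frames: dict[str, list[SensorFrame]] = field(default_factory=dict)
    task_boundaries: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    truth: dict[tuple[str, str], TaskTruth] = field(default_factory=dict)


def generate_session(profile: ParticipantProfile, med_state: str,
                     fs: float = SOURCE_FS, loss_rate: float = 0.0,
                     seed: int | np.random.SeedSequence = 0,
                     start: datetime | None = None,
                     noise_scale: float = 1.0,
                     repetitions: int = DEFAULT_REPETITIONS,
                     tasks: tuple[str, ...] = TASK_ORDER,
                     ) -> SyntheticSession:
    """Generate a full session: all six tasks per hand, in battery order.

    Tasks are separated by short rest gaps.  Transport loss drops whole
    payload-sized (32-sample) blocks, aligned to the stream start, with
    probability ``loss_rate`` each, so the surviving effective rate is about
    ``fs * (1 - loss_rate)``.
    """
    if not 0.0 <= loss_rate < 1.0:
        raise ValueError("loss_rate must be in [0, 1)")
    if start is None:
        start = datetime(2024, 1, 15, 9, 0, 0)
    t0_us = int(start.timestamp() * 1e6)
    tasks = tuple(validate_task(t) for t in tasks)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # one child per (hand, task) plus one per hand for loss
    children = root.spawn(len(HANDS) * (len(tasks) + 1))
    session = SyntheticSession(participant_id=profile.participant_id,
                               med_state=med_state, fs=fs,
                               session_datetime=start.isoformat(),
                               loss_rate=loss_rate)
    ci = 0
    gap_n = int(round(TASK_GAP_S * fs))
    for hand in HANDS:
        blocks: list[np.ndarray] = []  # (n, 11) per span
        boundaries: dict[str, tuple[int, int]] = {}
        cursor = 0  # sample index within the hand stream
        for ti, task in enumerate(tasks):
            channels, truth = generate_task_signal(
                task, profile, med_state, fs=fs, seed=children[ci],
                repetitions=repetitions, noise_scale=noise_scale)
            ci += 1
            mat = np.column_stack([channels[ch] for ch in CHANNELS])
            n_task = mat.shape[0]
            start_us = int(round(t0_us + cursor * 1e6 / fs))
            end_us = int(round(t0_us + (cursor + n_task - 1) * 1e6 / fs))
            boundaries[task] = (start_us, end_us)
            session.truth[(hand, task)] = truth
            blocks.append(mat)
            cursor += n_task
            if ti < len(tasks) - 1:
                rest_rng = np.random.default_rng(children[ci - 1].spawn(1)[0])
                rest = np.zeros((gap_n, len(CHANNELS)))
                rest[:, 8:11] = FLEX_BASELINE
                rest += noise_scale * 0.01 * rest_rng.standard_normal(rest.shape)
                blocks.append(rest)
                cursor += gap_n
        stream = np.vstack(blocks)
        n_total = stream.shape[0]
        times_us = np.round(t0_us + np.arange(n_total) * 1e6 / fs).astype(np.int64)
        keep = np.ones(n_total, dtype=bool)
        if loss_rate > 0:
            loss_rng = np.random.default_rng(children[ci])
            n_blocks = int(np.ceil(n_total / PAYLOAD_SAMPLES))
            dropped = loss_rng.random(n_blocks) < loss_rate
            keep = ~np.repeat(dropped, PAYLOAD_SAMPLES)[:n_total]
        ci += 1
        session.frames[hand] = [
            SensorFrame(float(times_us[i]), *stream[i])
            for i in np.flatnonzero(keep)
        ]
        session.task_boundaries[hand] = boundaries
    return session


def paired_sessions(profile: ParticipantProfile, n_days: int, seed: int,
                    fs: float = SOURCE_FS, loss_rate: float = 0.0,
                    noise_scale: float = 1.0,
                    first_day: datetime | None = None,
                    tasks: tuple[str, ...] = TASK_ORDER,
                    ) -> list[SyntheticSession]:
    """Pre/post-medication session pairs over ``n_days`` consecutive days.

    Emulates the study protocol of performing the battery before and after
    medication intake: the pre session at 09:00, the post at 14:00.
    """
    if first_day is None:
        first_day = datetime(2024, 1, 15)
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(2 * n_days))
    sessions = []
    for day in range(n_days):
        date = first_day + timedelta(days=day)
        for med_state, hour in (("pre", 9), ("post", 14)):
            sessions.append(generate_session(
                profile, med_state, fs=fs, loss_rate=loss_rate,
                seed=next(children), start=date.replace(hour=hour),
                noise_scale=noise_scale, tasks=tasks))
    return sessions
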