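"""Resampling, attitude estimation, and stream diagnostics.

Transport loss and ingest timestamping leave the raw streams irregular, so
all analysis starts by resampling each channel onto a uniform 64 Hz grid by
linear interpolation.  Content of interest lies below 10 Hz, well under the
32 Hz Nyquist limit of the analysis rate.  Attitude (pitch/roll) normally
arrives computed on-device; when only raw inertial channels are available it
is reconstructed with a complementary filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Uniform analysis rate in Hz.
ANALYSIS_FS = 64.0


@dataclass
class UniformSignal:
    """A uniformly sampled multi-channel signal.

    ``data`` maps channel name to a 1-D array; all channels share the grid
    ``t0 + k / fs`` (``t0`` in UTC microseconds, spacing in seconds).
    """

    fs: float
    t0: float
    data: dict[str, np.ndarray]

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.data.values())))

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.fs

    def times_s(self) -> np.ndarray:
        """Sample times in seconds relative to t0."""
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        if name == "gyro_mag":
            return np.sqrt(self.data["gx"] ** 2 + self.data["gy"] ** 2 + self.data["gz"] ** 2)
        return self.data[name]


def resample(times_us: np.ndarray, values: dict[str, np.ndarray] | np.ndarray,
             target_fs: float = ANALYSIS_FS) -> UniformSignal:
    """Linearly interpolate an irregular stream onto a uniform grid.

    Parameters
    ----------
    times_us
        Strictly increasing sample times in UTC microseconds.
    values
        Either a single 1-D array (stored under channel ``"x"``) or a mapping
        of channel name to 1-D array, all aligned with ``times_us``.
    target_fs
        Output rate in Hz (default 64).

    The output grid spans ``[t_first, t_last]``: samples at
    ``t_first + k / target_fs`` for ``k = 0 .. floor((t_last-t_first)*fs)``.
    """
    times_us = np.asarray(times_us, dtype=float)
    if times_us.ndim != 1 or len(times_us) < 2:
        raise ValueError("resampling requires at least 2 samples")
    if np.any(np.diff(times_us) <= 0):
        raise ValueError("times must be strictly increasing")
    if isinstance(values, np.ndarray):
        values = {"x": values}
    t_s = (times_us - times_us[0]) / 1e6
    n_out = int(np.floor(t_s[-1] * target_fs)) + 1
    grid = np.arange(n_out) / target_fs
    data = {}
    for name, v in values.items():
        v = np.asarray(v, dtype=float)
        if v.shape != times_us.shape:
            raise ValueError(f"channel {name!r} length {len(v)} != {len(times_us)} times")
        data[name] = np.interp(grid, t_s, v)
    return UniformSignal(fs=target_fs, t0=times_us[0], data=data)


def attitude_from_imu(ax: np.ndarray, ay: np.ndarray, az: np.ndarray,
                      gx: np.ndarray, gy: np.ndarray, fs: float,
                      blend: float = 0.98) -> tuple[np.ndarray, np.ndarray]:
    """Estimate pitch and roll (degrees) with a complementary filter.

    Gyroscope rates (deg/s; ``gx`` about the roll axis, ``gy`` about the
    pitch axis) are integrated and corrected each step toward the
    gravity-derived angles:

        angle <- blend * (angle + rate * dt) + (1 - blend) * angle_acc

    A 6-DoF IMU provides no heading reference, so yaw is not estimated.
    Zero-norm accelerometer samples carry the previous correction angle.
    Static gravity-aligned input (a = (0, 0, 1) g) yields 0 deg on both axes.
    """
    if not 0.0 <= blend <= 1.0:
        raise ValueError("blend must be in [0, 1]")
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    gx, gy = np.asarray(gx, dtype=float), np.asarray(gy, dtype=float)
    n = len(ax)
    dt = 1.0 / fs
    norm = np.sqrt(ax**2 + ay**2 + az**2)
    pitch_acc = np.degrees(np.arctan2(-ax, np.sqrt(ay**2 + az**2)))
    roll_acc = np.degrees(np.arctan2(ay, az))
    pitch = np.empty(n)
    roll = np.empty(n)
    # Initialize from the first valid accelerometer sample.
    p_prev = pitch_acc[0] if norm[0] > 0 else 0.0
    r_prev = roll_acc[0] if norm[0] > 0 else 0.0
    pitch[0], roll[0] = p_prev, r_prev
    pa_prev, ra_prev = p_prev, r_prev
    for k in range(1, n):
        if norm[k] > 0:
            pa_prev, ra_prev = pitch_acc[k], roll_acc[k]
        p_prev = blend * (p_prev + gy[k] * dt) + (1 - blend) * pa_prev
        r_prev = blend * (r_prev + gx[k] * dt) + (1 - blend) * ra_prev
        pitch[k], roll[k] = p_prev, r_prev
    return pitch, roll


def effective_rate(times_or_count, window_duration_s: float) -> float:
    """Surviving samples per second over a window (Hz).

    ``times_or_count`` may be a sample count or a sequence of sample times.
    Empty input yields 0.
    """
    if window_duration_s <= 0:
        raise ValueError("window_duration_s must be positive")
    n = times_or_count if isinstance(times_or_count, (int, np.integer)) else len(times_or_count)
    return n / window_duration_s
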