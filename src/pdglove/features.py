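"""Task-specific movement features and medication-state labels.

Three symptom families drive the feature set:

* **Tremor** — rhythmic oscillation; captured by band energy in 5-10 Hz.
* **Levodopa-induced dyskinesia** — involuntary movement concentrated in
  2-5 Hz; captured by band energy in that band.
* **Bradykinesia** — progressive amplitude reduction and timing
  irregularity across repeated movements; captured by peak-valley analysis
  of the repetition train (amplitudes, inter-tap intervals, decrement
  slope), compared between the start, middle, and end thirds of the
  activity window.

Kinetic task windows are split into three equal sections (start/middle/end)
and stationary task recordings into two halves; spectral and peak-valley
statistics are computed per whole window and per section.  Feature ids
follow ``<task>_<hand>_<channel>_<section>_<stat>`` so vectors are keyed by
name, never by position.

Medication-state labels come from the daily questionnaire's
hours-since-intake bins: the 0-3 h bin maps to label 0 (pre-medication) and
the 4+ h bin to label 1 (post-medication).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from pdglove.preprocess import UniformSignal
from pdglove.tasks import FEATURE_CHANNELS, KINETIC_TASKS, validate_hand, validate_task

#: Tremor band in Hz (half-open, [lo, hi)).
TREMOR_BAND = (5.0, 10.0)
#: Levodopa-induced dyskinesia band in Hz.
DYSKINESIA_BAND = (2.0, 5.0)

KINETIC_SECTIONS = ("start", "mid", "end")
STATIONARY_SECTIONS = ("h1", "h2")


def _periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Single rectangular-window periodogram of the mean-removed signal.

    Returns (freqs, power) with power normalized so that the sum over all
    bins equals the total mean-removed power ``mean((x - mean)^2)``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2 / n**2
    # One-sided spectrum: double everything except DC and (even n) Nyquist.
    if n % 2 == 0:
        spec[1:-1] *= 2.0
    else:
        spec[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def band_energy(signal: np.ndarray, fs: float, lo_hz: float, hi_hz: float) -> float:
    """Mean-removed signal power in the frequency band ``[lo, hi)``.

    ``hi == fs/2`` additionally includes the Nyquist bin, so a disjoint band
    partition covering ``[0, fs/2]`` sums exactly to the total mean-removed
    power (Parseval).
    """
    if hi_hz > fs / 2:
        raise ValueError(f"band edge {hi_hz} Hz exceeds Nyquist {fs / 2} Hz")
    if lo_hz < 0 or lo_hz >= hi_hz:
        raise ValueError("band must satisfy 0 <= lo < hi")
    freqs, spec = _periodogram(signal, fs)
    mask = (freqs >= lo_hz) & (freqs < hi_hz)
    if hi_hz == fs / 2:
        mask |= freqs == hi_hz
    return float(spec[mask].sum())


class SpectralSummary(NamedTuple):
    mean_frequency: float
    peak_frequency: float
    has_power: bool


def spectral_summary(signal: np.ndarray, fs: float) -> SpectralSummary:
    """Power-weighted spectral centroid and argmax frequency.

    A signal with zero mean-removed power yields ``(0, 0)`` with the
    ``has_power`` flag cleared.
    """
    freqs, spec = _periodogram(signal, fs)
    total = spec.sum()
    if total <= 0:
        return SpectralSummary(0.0, 0.0, False)
    centroid = float((freqs * spec).sum() / total)
    peak = float(freqs[int(np.argmax(spec))])
    return SpectralSummary(centroid, peak, True)


@dataclass
class PeakValleySeries:
    """Peaks and interleaved valleys of a repetition train.

    ``amplitudes[k]`` is peak ``k`` minus the mean of its adjacent valley
    values (one-sided at the ends); ``intervals`` are successive peak
    spacings in seconds, so ``len(intervals) == len(peaks) - 1``.
    """

    peak_times: np.ndarray
    peak_values: np.ndarray
    valley_times: np.ndarray
    valley_values: np.ndarray
    amplitudes: np.ndarray
    intervals: np.ndarray

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)

    def amplitude_slope(self) -> float:
        """Least-squares slope of amplitude vs. peak time (units/s).

        Bradykinetic decrement shows as a negative slope.  Fewer than two
        peaks yield 0.
        """
        if self.n_peaks < 2:
            return 0.0
        return float(np.polyfit(self.peak_times, self.amplitudes, 1)[0])


def peak_valley(signal: np.ndarray, fs: float, min_prominence: float | None = None,
                min_separation_s: float = 0.2) -> PeakValleySeries:
    """Peak-valley analysis of a repetition train.

    Local maxima with prominence >= ``min_prominence`` (default: a quarter
    of the 5th-95th percentile range) and spacing >= ``min_separation_s``
    are peaks; the minimum between consecutive peaks is a valley.
    """
    x = np.asarray(signal, dtype=float)
    if min_prominence is None:
        p5, p95 = np.percentile(x, [5, 95]) if len(x) else (0.0, 0.0)
        min_prominence = 0.25 * (p95 - p5)
    distance = max(1, int(round(min_separation_s * fs)))
    peaks, _ = find_peaks(x, prominence=min_prominence or None, distance=distance)
    if len(peaks) == 0:
        empty = np.empty(0)
        return PeakValleySeries(empty, empty, empty, empty, empty, empty)
    valley_idx = np.array(
        [peaks[i] + int(np.argmin(x[peaks[i]:peaks[i + 1] + 1])) for i in range(len(peaks) - 1)],
        dtype=int,
    )
    t = np.arange(len(x)) / fs
    vvals = x[valley_idx] if len(valley_idx) else np.empty(0)
    amplitudes = np.empty(len(peaks))
    for k in range(len(peaks)):
        adjacent = []
        if k - 1 >= 0 and k - 1 < len(vvals):
            adjacent.append(vvals[k - 1])
        if k < len(vvals):
            adjacent.append(vvals[k])
        amplitudes[k] = x[peaks[k]] - np.mean(adjacent) if adjacent else x[peaks[k]]
    return PeakValleySeries(
        peak_times=t[peaks],
        peak_values=x[peaks],
        valley_times=t[valley_idx] if len(valley_idx) else np.empty(0),
        valley_values=vvals,
        amplitudes=amplitudes,
        intervals=np.diff(t[peaks]),
    )


def split_sections(segment: np.ndarray, k: int) -> list[np.ndarray]:
    """Split a segment into ``k`` contiguous equal-duration sections.

    Lengths differ by at most one sample (earlier sections take the
    remainder) and the sections cover the segment exactly.
    """
    segment = np.asarray(segment)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(segment) < k:
        raise ValueError(f"segment of {len(segment)} samples cannot be split into {k} sections")
    return np.array_split(segment, k)


@dataclass
class FeatureVector:
    """A named feature map with its session labels.

    ``med_state`` is 0 (pre-medication) or 1 (post-medication); ``None``
    when unlabeled.  Absent-peak statistics are the sentinel 0, with the
    ``peak_count`` feature recording how many peaks were found.
    """

    features: dict[str, float]
    participant_id: str = ""
    task: str = ""
    hand: str = ""
    session_datetime: str = ""
    med_state: int | None = None

    def __post_init__(self) -> None:
        bad = [k for k, v in self.features.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad[:5]}")


def _section_features(x: np.ndarray, fs: float, kinetic: bool,
                      tremor_band: tuple[float, float],
                      dysk_band: tuple[float, float]) -> dict[str, float]:
    out: dict[str, float] = {}
    out["rms"] = float(np.sqrt(np.mean(x**2)))
    ms = spectral_summary(x, fs)
    out["mean_freq"] = ms.mean_frequency
    out["peak_freq"] = ms.peak_frequency
    out["has_power"] = float(ms.has_power)
    out["tremor_band"] = band_energy(x, fs, *tremor_band)
    out["dysk_band"] = band_energy(x, fs, *dysk_band)
    if kinetic:
        pv = peak_valley(x, fs)
        n = pv.n_peaks
        out["peak_count"] = float(n)
        out["amp_mean"] = float(pv.amplitudes.mean()) if n >= 1 else 0.0
        out["amp_std"] = float(pv.amplitudes.std()) if n >= 2 else 0.0
        out["int_mean"] = float(pv.intervals.mean()) if n >= 2 else 0.0
        out["int_std"] = float(pv.intervals.std()) if n >= 3 else 0.0
        out["amp_slope"] = pv.amplitude_slope()
        out["amp_delta"] = float(pv.amplitudes[-1] - pv.amplitudes[0]) if n >= 2 else 0.0
        out["int_delta"] = float(pv.intervals[-1] - pv.intervals[0]) if n >= 3 else 0.0
    return out


def extract_features(segment: UniformSignal, task: str, hand: str,
                     tremor_band: tuple[float, float] = TREMOR_BAND,
                     dysk_band: tuple[float, float] = DYSKINESIA_BAND,
                     **labels) -> FeatureVector:
    """Compute the task-specific feature vector for one windowed segment.

    ``segment`` is the activity-windowed (kinetic tasks) or whole
    (stationary tasks) uniformly sampled signal.  Channels analyzed per
    task: index flexion for FT; index/thumb/middle flexion for OC; pitch and
    roll for HF and FN; pitch, roll, and gyroscope magnitude for HH and RH.
    """
    validate_task(task)
    validate_hand(hand)
    kinetic = task in KINETIC_TASKS
    fs = segment.fs
    features: dict[str, float] = {}
    prefix = task.lower()
    for ch in FEATURE_CHANNELS[task]:
        x = segment.channel(ch)
        sections: list[tuple[str, np.ndarray]] = []
        if kinetic:
            sections.append(("whole", x))
            sections.extend(zip(KINETIC_SECTIONS, split_sections(x, 3)))
        else:
            sections.extend(zip(STATIONARY_SECTIONS, split_sections(x, 2)))
        for sec_name, sec in sections:
            stats = _section_features(sec, fs, kinetic, tremor_band, dysk_band)
            for stat, value in stats.items():
                features[f"{prefix}_{hand}_{ch}_{sec_name}_{stat}"] = value
    return FeatureVector(features=features, task=task, hand=hand, **labels)


# hours-since-intake questionnaire bins -> binary medication state
_BIN_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:[-–]\s*(\d+(?:\.\d+)?))?\s*(\+)?\s*h?(?:ours?)?\s*$",
                     re.IGNORECASE)


def bin_medication_label(hours_since_intake_bin: str | float, invert: bool = False) -> int:
    """Map an hours-since-intake questionnaire bin to a medication state.

    The 0-3 h bin maps to 0 (pre-medication) and the 4+ h bin to 1
    (post-medication); numeric sub-bins are resolved by containment (hours
    < 4 fall in the 0-3 h bin).  ``invert`` swaps the mapping for
    deployments that label the recent-intake bin as post-medication.
    """
    if isinstance(hours_since_intake_bin, (int, float)) and not isinstance(hours_since_intake_bin, bool):
        hours = float(hours_since_intake_bin)
        if hours < 0:
            raise ValueError("hours since intake cannot be negative")
        label = 0 if hours < 4 else 1
        return 1 - label if invert else label
    m = _BIN_RE.match(str(hours_since_intake_bin))
    if not m:
        raise ValueError(f"unrecognized medication-intake bin {hours_since_intake_bin!r}")
    lo = float(m.group(1))
    label = 0 if lo < 4 else 1
    return 1 - label if invert else label


LABEL_COLUMNS = ("participant_id", "task", "hand", "session_datetime", "med_state")


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Assemble feature vectors into a tidy table.

    One row per (session, task, hand); label columns first, then the union
    of feature columns (missing combinations become NaN; vectors of the same
    task/hand share names so tables are dense in practice).
    """
    rows = []
    for v in vectors:
        row = {
            "participant_id": v.participant_id,
            "task": v.task,
            "hand": v.hand,
            "session_datetime": v.session_datetime,
            "med_state": v.med_state,
        }
        row.update(v.features)
        rows.append(row)
    df = pd.DataFrame(rows)
    feats = [c for c in df.columns if c not in LABEL_COLUMNS]
    return df[[*LABEL_COLUMNS, *sorted(feats)]]


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str, "session_datetime": str})
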