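"""Energy-based adaptive activity windowing.

Kinetic task recordings contain rest before and after the prompted movement
(participants often finish early).  A modified voice-activity-detector
isolates the movement: short-time energy is computed over sliding frames of
the task's primary channel, and frames exceeding an adaptive threshold

    T = E_min + alpha * (E_mean - E_min)

are marked active.  Adjacent active runs separated by short gaps are merged
and too-short segments dropped; the highest-total-energy segment is the
*primary* activity window handed to feature extraction.  Stationary tasks
(fixed 10 s postures) are used whole and bypass the detector.

Energies and the threshold both scale with the square of a signal gain and
each frame's mean is removed before squaring, so segment boundaries are
invariant to gain and constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pdglove.preprocess import UniformSignal

#: Threshold floor guarding against an exactly-zero minimum energy.
_EPS = 1e-12

# Defaults sized so tap trains at ~1-3 Hz do not fragment.
FRAME_LEN_S = 0.25
HOP_S = 0.125
ALPHA = 0.3
MIN_SEG_S = 0.5
MERGE_GAP_S = 0.5


@dataclass(frozen=True)
class ActivitySegment:
    """A detected activity interval, in seconds relative to task start."""

    start_s: float
    end_s: float
    energy: float  # summed frame energy within the segment

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def iou(self, other_start: float, other_end: float) -> float:
        """Intersection-over-union with another interval."""
        inter = max(0.0, min(self.end_s, other_end) - max(self.start_s, other_start))
        union = max(self.end_s, other_end) - min(self.start_s, other_start)
        return inter / union if union > 0 else 0.0


def _as_array(signal, channel: str | None) -> tuple[np.ndarray, float]:
    if isinstance(signal, UniformSignal):
        name = channel if channel is not None else next(iter(signal.data))
        return signal.channel(name), signal.fs
    raise TypeError("signal must be a UniformSignal; pass arrays via UniformSignal(fs, 0, {'x': arr})")


def frame_energies(signal: UniformSignal, frame_len_s: float = FRAME_LEN_S,
                   hop_s: float = HOP_S, channel: str | None = None) -> np.ndarray:
    """Short-time energy per sliding frame.

    ``E_i`` is the mean of squared mean-removed samples within frame ``i``
    (i.e. the frame variance), so a constant offset carries no energy.
    Frame count is ``floor((N - L) / H) + 1``.
    """
    x, fs = _as_array(signal, channel)
    L = int(round(frame_len_s * fs))
    H = int(round(hop_s * fs))
    if L < 2:
        raise ValueError("frame must span at least 2 samples")
    if H < 1 or H > L:
        raise ValueError("hop must satisfy 1 sample <= hop <= frame length")
    if len(x) < L:
        raise ValueError(f"signal ({len(x)} samples) shorter than one frame ({L})")
    n_frames = (len(x) - L) // H + 1
    idx = np.arange(L)[None, :] + H * np.arange(n_frames)[:, None]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)
    return (frames**2).mean(axis=1)


def adaptive_threshold(energies: np.ndarray, alpha: float = ALPHA) -> float:
    """Threshold between minimum and mean frame energy.

    ``T = E_min + alpha * (E_mean - E_min)`` with ``E_min`` floored at a
    small epsilon.  At ``alpha -> 1`` the threshold approaches the mean.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.size == 0:
        raise ValueError("energies must be nonempty")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    e_min = max(float(energies.min()), _EPS)
    e_mean = float(energies.mean())
    return e_min + alpha * (e_mean - e_min)


def detect_activity(signal: UniformSignal, frame_len_s: float = FRAME_LEN_S,
                    hop_s: float = HOP_S, alpha: float = ALPHA,
                    min_seg_s: float = MIN_SEG_S, merge_gap_s: float = MERGE_GAP_S,
                    channel: str | None = None,
                    ) -> tuple[list[ActivitySegment], ActivitySegment | None]:
    """Segment movement activity in a task recording.

    Returns ``(segments, primary)`` where ``primary`` is the segment with the
    highest total frame energy, or ``None`` when nothing exceeds threshold.
    """
    energies = frame_energies(signal, frame_len_s, hop_s, channel=channel)
    T = adaptive_threshold(energies, alpha)
    active = energies > T
    if not active.any():
        return [], None
    # Runs of active frames -> candidate (first_frame, last_frame) intervals.
    edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2] - 1))
    # Merge runs whose uncovered time gap is shorter than merge_gap.
    merged = [runs[0]]
    for a, b in runs[1:]:
        gap_s = a * hop_s - (merged[-1][1] * hop_s + frame_len_s)
        if gap_s < merge_gap_s:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    segments = []
    for a, b in merged:
        start = a * hop_s
        end = b * hop_s + frame_len_s
        if end - start >= min_seg_s:
            segments.append(ActivitySegment(start, end, float(energies[a:b + 1].sum())))
    if not segments:
        return [], None
    primary = max(segments, key=lambda s: s.energy)
    return segments, primary
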