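"""Wire payload codec, topic scheme, and ingest-side batching buffer.

The gloves stream sensor values over a publish-subscribe transport whose
payloads must be character data.  Each payload carries exactly 32 samples of
all 11 channels: every value is rendered as decimal text and terminated with
a semicolon, concatenated channel-major over the fixed channel order (32
values for channel 0, then 32 for channel 1, ...), 352 value fields total.
Timestamps are not carried on the wire; the ingest side assigns UTC
microsecond timestamps at decode, spacing samples at the nominal source rate
backwards from the arrival time.

The hub buffers decoded records and writes them out in batches of 128.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from pdglove.tasks import CHANNELS, validate_hand, validate_task

#: Samples per channel in one wire payload.
PAYLOAD_SAMPLES = 32

#: Records per ingest batch.
BATCH_SIZE = 128

#: Topic prefix of the glove telemetry dialect.
TOPIC_PREFIX = "itex"

N_CHANNELS = len(CHANNELS)
_N_FIELDS = PAYLOAD_SAMPLES * N_CHANNELS  # 352


class MalformedPayloadError(ValueError):
    """Raised when a payload body does not obey the wire grammar."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (field offset {offset})"
        super().__init__(message)


@dataclass(frozen=True)
class SensorFrame:
    """One timestamped 11-channel sample.

    ``t`` is UTC microseconds (float; sub-microsecond spacing arises when the
    nominal rate does not divide one second).  Acceleration is in g,
    gyroscope in deg/s, pitch/roll in degrees, flexion in ADC volts.
    """

    t: float
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float
    pitch: float
    roll: float
    flex_index: float
    flex_thumb: float
    flex_middle: float

    def values(self) -> tuple[float, ...]:
        """The 11 channel values in wire order (no timestamp)."""
        return tuple(getattr(self, ch) for ch in CHANNELS)


@dataclass(frozen=True)
class Payload:
    """One encoded wire message: 32 samples per channel plus routing."""

    hand: str
    task: str
    body: str
    n_samples: int = PAYLOAD_SAMPLES

    @property
    def topic(self) -> str:
        return topic_for(self.hand, self.task)


def _render(value: float) -> str:
    # Shortest decimal that round-trips at single precision: the glove
    # microcontroller computes in float32.
    return np.format_float_positional(np.float32(value), unique=True, trim="-")


def encode_payload(frames: Iterable[SensorFrame]) -> str:
    """Encode exactly 32 frames into a payload body string.

    Values are laid out channel-major: the 32 samples of channel 0, then the
    32 samples of channel 1, and so on over the fixed 11-channel order.  Each
    value field is semicolon-terminated, giving 352 fields.
    """
    frames = list(frames)
    if len(frames) != PAYLOAD_SAMPLES:
        raise ValueError(f"payload requires exactly {PAYLOAD_SAMPLES} frames, got {len(frames)}")
    parts: list[str] = []
    for ch in CHANNELS:
        for frame in frames:
            parts.append(_render(getattr(frame, ch)))
            parts.append(";")
    return "".join(parts)


def decode_payload(body: str, arrival_time: float, nominal_fs: float) -> list[SensorFrame]:
    """Decode a payload body into 32 timestamped frames.

    Timestamps are assigned at ingest: samples are spaced ``1/nominal_fs``
    apart, the last one coinciding with ``arrival_time`` (UTC microseconds).

    Raises :class:`MalformedPayloadError` identifying the field offset when
    the body has the wrong field count or a non-numeric field.
    """
    if nominal_fs <= 0:
        raise ValueError("nominal_fs must be positive")
    fields = body.split(";")
    if fields and fields[-1] == "":
        fields = fields[:-1]  # grammar terminates every field with ';'
    else:
        raise MalformedPayloadError("body does not end with field terminator ';'")
    if len(fields) != _N_FIELDS:
        raise MalformedPayloadError(
            f"expected {_N_FIELDS} value fields, found {len(fields)}", offset=len(fields)
        )
    values = np.empty((N_CHANNELS, PAYLOAD_SAMPLES))
    for i, text in enumerate(fields):
        try:
            values[i // PAYLOAD_SAMPLES, i % PAYLOAD_SAMPLES] = float(text)
        except ValueError:
            raise MalformedPayloadError(f"non-numeric field {text!r}", offset=i) from None
    dt_us = 1e6 / nominal_fs
    frames = []
    for k in range(PAYLOAD_SAMPLES):
        t = arrival_time - (PAYLOAD_SAMPLES - 1 - k) * dt_us
        frames.append(SensorFrame(t, *(values[c, k] for c in range(N_CHANNELS))))
    return frames


def topic_for(hand: str, task: str) -> str:
    """Topic string for a (hand, task) route, e.g. ``itex/left/FT``."""
    return f"{TOPIC_PREFIX}/{validate_hand(hand)}/{validate_task(task)}"


def parse_topic(topic: str) -> tuple[str, str]:
    """Inverse of :func:`topic_for`."""
    parts = topic.split("/")
    if len(parts) != 3 or parts[0] != TOPIC_PREFIX:
        raise ValueError(f"not a glove telemetry topic: {topic!r}")
    return validate_hand(parts[1]), validate_task(parts[2])


@dataclass
class IngestBuffer:
    """Arrival-order batching buffer for decoded records.

    ``push`` yields completed batches of exactly ``batch_size`` records;
    ``flush`` emits whatever remains at session end.  No record is lost or
    duplicated and order is preserved.
    """

    batch_size: int = BATCH_SIZE
    _pending: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def push(self, records: Iterable) -> Iterator[list]:
        for record in records:
            self._pending.append(record)
            if len(self._pending) == self.batch_size:
                batch, self._pending = self._pending, []
                yield batch

    def flush(self) -> list:
        batch, self._pending = self._pending, []
        return batch


def ingest_buffer(records: Iterable, batch_size: int = BATCH_SIZE) -> tuple[list[list], list]:
    """Batch a finite record stream: full batches plus the final remainder."""
    buf = IngestBuffer(batch_size)
    batches = list(buf.push(records))
    return batches, buf.flush()
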