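"""Session artifact IO: per-hand CSV exports and daily questionnaires.

At the end of a session, each hand's stream is exported to a CSV holding the
ISO-8601 timestamp, the 11 channel values, the activity (task) tag, and the
interval to the previous sample.  Files live in a folder named for the
session date, with file names combining hand and session date-time, e.g.
``2024-01-02/left_2024-01-02T09-00-00.csv``.  The daily questionnaire is a
plain-text ``key: value`` file in the same folder.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from pdglove.features import bin_medication_label
from pdglove.synth import SyntheticSession
from pdglove.tasks import CHANNELS, TASK_CODES, validate_hand, validate_task


class SchemaError(ValueError):
    """A session CSV is missing or duplicating required columns."""


class IntegrityError(ValueError):
    """A session CSV violates ordering or interval consistency."""


class TaskNotFoundError(KeyError):
    """The requested task does not appear in the export."""


REQUIRED_COLUMNS = ("timestamp", *CHANNELS, "task", "inter_sample_interval")


@dataclass
class SessionExport:
    """One hand's exported session table.

    ``rows`` columns: ``timestamp_us`` (int, UTC microseconds), the 11
    channels, ``task`` (a task code or ``"rest"``), and
    ``inter_sample_interval`` (seconds to the previous row; 0 for the
    first).
    """

    hand: str
    participant_id: str
    session_datetime: str  # ISO-8601
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        validate_hand(self.hand)


def from_session(session: SyntheticSession, hand: str) -> SessionExport:
    """Build the export table for one hand of a generated session.

    Rows are tagged with the task code whose boundary interval contains
    their timestamp, or ``"rest"`` between tasks.
    """
    frames = session.frames[validate_hand(hand)]
    t = np.array([f.t for f in frames], dtype=np.int64)
    data = {"timestamp_us": t}
    for i, ch in enumerate(CHANNELS):
        data[ch] = np.array([f.values()[i] for f in frames])
    tags = np.full(len(frames), "rest", dtype=object)
    for task, (start_us, end_us) in session.task_boundaries[hand].items():
        tags[(t >= start_us) & (t <= end_us)] = task
    data["task"] = tags
    interval = np.zeros(len(frames))
    if len(frames) > 1:
        interval[1:] = np.diff(t) / 1e6
    data["inter_sample_interval"] = interval
    return SessionExport(hand=hand, participant_id=session.participant_id,
                         session_datetime=session.session_datetime,
                         rows=pd.DataFrame(data))


def _file_stamp(session_datetime: str) -> tuple[str, str]:
    dt = datetime.fromisoformat(session_datetime)
    return dt.strftime("%Y-%m-%d"), dt.strftime("%Y-%m-%dT%H-%M-%S")


def session_path(root: Path | str, hand: str, session_datetime: str) -> Path:
    """Export path: date-named folder, hand + date-time file name."""
    day, stamp = _file_stamp(session_datetime)
    return Path(root) / day / f"{hand}_{stamp}.csv"


def write_session(export: SessionExport, root: Path | str) -> Path:
    """Write one hand's session CSV; returns the file path."""
    path = session_path(root, export.hand, export.session_datetime)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = export.rows.copy()
    ts = pd.to_datetime(df["timestamp_us"], unit="us")
    out = pd.DataFrame({"timestamp": ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%f")})
    for ch in CHANNELS:
        out[ch] = df[ch].map(repr)  # repr round-trips float64 exactly
    out["task"] = df["task"]
    out["inter_sample_interval"] = df["inter_sample_interval"].map(repr)
    out.to_csv(path, index=False)
    return path


def read_session(path: Path | str, participant_id: str = "") -> SessionExport:
    """Read a session CSV back into a :class:`SessionExport`.

    Raises :class:`SchemaError` on missing/duplicate columns and
    :class:`IntegrityError` on unordered timestamps or inconsistent
    inter-sample intervals.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"task": str}, float_precision="round_trip")
    if len(df.columns) != len(set(df.columns)):
        raise SchemaError(f"duplicate columns in {path.name}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} in {path.name}")
    unknown_tags = set(df["task"]) - TASK_CODES - {"rest"}
    if unknown_tags:
        raise SchemaError(f"unknown task tags {sorted(unknown_tags)} in {path.name}")
    t_us = pd.to_datetime(df["timestamp"], format="%Y-%m-%dT%H:%M:%S.%f").astype(np.int64) // 1000
    if np.any(np.diff(t_us) <= 0):
        raise IntegrityError(f"timestamps not strictly increasing in {path.name}")
    interval = df["inter_sample_interval"].astype(float).to_numpy()
    expected = np.concatenate(([interval[0]], np.diff(t_us) / 1e6)) if len(df) else interval
    if len(df) > 1 and np.max(np.abs(interval[1:] - expected[1:])) > 1e-6:
        raise IntegrityError(f"inter_sample_interval inconsistent with timestamps in {path.name}")
    # reconstruct session datetime from the file stamp (hand_YYYY-MM-DDTHH-MM-SS)
    hand = path.stem.split("_")[0]
    stamp = path.stem.split("_", 1)[1]
    day, clock = stamp.split("T")
    session_dt = f"{day}T{clock.replace('-', ':')}"
    rows = pd.DataFrame({"timestamp_us": t_us.to_numpy()})
    for ch in CHANNELS:
        rows[ch] = df[ch].astype(float)
    rows["task"] = df["task"]
    rows["inter_sample_interval"] = interval
    return SessionExport(hand=hand, participant_id=participant_id,
                         session_datetime=session_dt, rows=rows)


def extract_task(export: SessionExport, task: str) -> pd.DataFrame:
    """The contiguous rows tagged with ``task``, original timestamps kept."""
    validate_task(task)
    mask = (export.rows["task"] == task).to_numpy()
    if not mask.any():
        raise TaskNotFoundError(f"task {task!r} not present in {export.hand} export")
    return export.rows[mask].copy()


@dataclass
class Questionnaire:
    """Daily self-report: symptom and sleep ordinals plus the
    hours-since-medication-intake bin driving the session label."""

    tremor_report: int = 0        # 0 (none) .. 4 (severe)
    dyskinesia_report: int = 0    # 0 .. 4
    sleep_quality: int = 2        # 0 (poor) .. 4 (excellent)
    med_intake_bin: str = "0-3 h"

    @property
    def med_state(self) -> int:
        return bin_medication_label(self.med_intake_bin)


def write_questionnaire(q: Questionnaire, root: Path | str, session_datetime: str) -> Path:
    day, stamp = _file_stamp(session_datetime)
    path = Path(root) / day / f"questionnaire_{stamp}.txt"
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"tremor_report: {q.tremor_report}",
             f"dyskinesia_report: {q.dyskinesia_report}",
             f"sleep_quality: {q.sleep_quality}",
             f"med_intake_bin: {q.med_intake_bin}"]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_questionnaire(path: Path | str) -> Questionnaire:
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if ":" in line:
            key, value = line.split(":", 1)
            fields[key.strip()] = value.strip()
    return Questionnaire(
        tremor_report=int(fields.get("tremor_report", 0)),
        dyskinesia_report=int(fields.get("dyskinesia_report", 0)),
        sleep_quality=int(fields.get("sleep_quality", 2)),
        med_intake_bin=fields.get("med_intake_bin", "0-3 h"),
    )
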