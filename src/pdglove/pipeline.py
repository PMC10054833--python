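"""End-to-end orchestration: simulate -> ingest -> export -> features -> classify.

``run_pipeline`` drives the whole sensor-to-decision path on synthetic
participants: generated sessions are encoded into wire payloads, decoded and
batched by the ingest buffer, exported to per-hand CSVs with questionnaires,
read back, resampled to the 64 Hz analysis rate, activity-windowed (kinetic
tasks), reduced to feature vectors, and classified for medication state.
All artifacts (session CSVs, feature table, evaluation report, manifest)
are written under the configured output directory, and a fixed seed makes
the run reproducible end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pdglove import codec, windowing
from pdglove.classify import EvaluationReport, assemble_dataset, split_dataset, train_and_evaluate
from pdglove.codec import IngestBuffer, decode_payload, encode_payload
from pdglove.features import (
    DYSKINESIA_BAND,
    TREMOR_BAND,
    FeatureVector,
    extract_features,
    feature_table,
    write_feature_table,
)
from pdglove.preprocess import ANALYSIS_FS, UniformSignal, resample
from pdglove.session_io import (
    Questionnaire,
    SessionExport,
    extract_task,
    from_session,
    read_questionnaire,
    read_session,
    session_path,
    write_questionnaire,
    write_session,
)
from pdglove.synth import (
    SOURCE_FS,
    ParticipantProfile,
    SyntheticSession,
    generate_session,
    paired_sessions,
    random_profile,
)
from pdglove.tasks import CHANNELS, HANDS, KINETIC_TASKS, PRIMARY_CHANNEL, TASK_ORDER


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults emulate the feasibility-study conditions: four mild-to-moderate
    participants using the system daily for a week, before and after
    medication intake, with a glove source rate of 128 Hz and transport loss
    bringing the effective rate into the mid-80s Hz.
    """

    n_participants: int = 4
    days: int = 7                      # pre/post session pairs per participant
    seed: int = 0
    fs: float = SOURCE_FS
    loss_rate: float = 0.345
    noise_scale: float = 1.0
    severity_range: tuple[float, float] = (0.2, 0.8)
    suppression_range: tuple[float, float] = (0.4, 0.9)
    frame_len_s: float = windowing.FRAME_LEN_S
    hop_s: float = windowing.HOP_S
    alpha: float = windowing.ALPHA
    min_seg_s: float = windowing.MIN_SEG_S
    merge_gap_s: float = windowing.MERGE_GAP_S
    tremor_band: tuple[float, float] = TREMOR_BAND
    dysk_band: tuple[float, float] = DYSKINESIA_BAND
    tasks: tuple[str, ...] = TASK_ORDER
    model_set: tuple[str, ...] | None = None
    train_fraction: float = 0.8
    compute_importance: bool = True
    output_dir: str = "pdglove_run"

    def validate(self) -> None:
        if self.n_participants < 1 or self.days < 1:
            raise ValueError("n_participants and days must be >= 1")
        if not 0.0 <= self.loss_rate < 1.0:
            raise ValueError("loss_rate must be in [0, 1)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.fs <= 20.0:
            raise ValueError("fs must exceed twice the maximum tremor frequency (10 Hz)")
        unknown = set(self.tasks) - set(TASK_ORDER)
        if unknown:
            raise ValueError(f"unknown tasks {sorted(unknown)}")
        windowing.adaptive_threshold(np.ones(3), self.alpha)  # range check


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _slice_signal(signal: UniformSignal, start_s: float, end_s: float) -> UniformSignal:
    a = max(0, int(np.floor(start_s * signal.fs)))
    b = min(signal.n_samples, int(np.ceil(end_s * signal.fs)) + 1)
    return UniformSignal(fs=signal.fs, t0=signal.t0 + a / signal.fs * 1e6,
                         data={k: v[a:b] for k, v in signal.data.items()})


def window_task(uniform: UniformSignal, task: str, config: RunConfig | None = None) -> UniformSignal:
    """Apply adaptive activity windowing to a kinetic task signal.

    Kinetic tasks are cut to the primary (highest-energy) activity segment
    detected on the task's primary channel; stationary tasks are returned
    whole.  When nothing exceeds threshold the whole signal is kept.
    """
    if task not in KINETIC_TASKS:
        return uniform
    cfg = config or RunConfig()
    _, primary = windowing.detect_activity(
        uniform, frame_len_s=cfg.frame_len_s, hop_s=cfg.hop_s, alpha=cfg.alpha,
        min_seg_s=cfg.min_seg_s, merge_gap_s=cfg.merge_gap_s,
        channel=PRIMARY_CHANNEL[task])
    if primary is None:
        return uniform
    return _slice_signal(uniform, primary.start_s, primary.end_s)


def features_from_export(export: SessionExport, med_state: int,
                         config: RunConfig | None = None) -> list[FeatureVector]:
    """Resample, window, and featurize every task present in an export."""
    cfg = config or RunConfig()
    vectors = []
    for task in cfg.tasks:
        try:
            rows = extract_task(export, task)
        except KeyError:
            continue
        if len(rows) < 2:
            continue
        uniform = resample(rows["timestamp_us"].to_numpy(),
                           {ch: rows[ch].to_numpy() for ch in CHANNELS},
                           target_fs=ANALYSIS_FS)
        segment = window_task(uniform, task, cfg)
        vectors.append(extract_features(
            segment, task, export.hand,
            tremor_band=cfg.tremor_band, dysk_band=cfg.dysk_band,
            participant_id=export.participant_id,
            session_datetime=export.session_datetime,
            med_state=med_state))
    return vectors


def features_from_session(session: SyntheticSession,
                          config: RunConfig | None = None) -> list[FeatureVector]:
    """Direct path from a generated session to feature vectors (no CSV/codec)."""
    med = 0 if session.med_state == "pre" else 1
    vectors = []
    for hand in HANDS:
        export = from_session(session, hand)
        export = SessionExport(hand=hand, participant_id=session.participant_id,
                               session_datetime=session.session_datetime,
                               rows=export.rows)
        vectors.extend(features_from_export(export, med, config))
    return vectors


def simulate_feature_table(profiles: list[ParticipantProfile], days: int, seed: int,
                           config: RunConfig | None = None) -> pd.DataFrame:
    """Feature table for pre/post session pairs of many participants.

    Uses the direct generation path (no codec/CSV round trip); suited to
    classification experiments where the transport plumbing is not under
    study.
    """
    cfg = config or RunConfig()
    root = np.random.SeedSequence(seed)
    vectors: list[FeatureVector] = []
    for profile, child in zip(profiles, root.spawn(len(profiles))):
        for session in paired_sessions(profile, days, seed=int(child.generate_state(1)[0] % 2**31),
                                       fs=cfg.fs, loss_rate=cfg.loss_rate,
                                       noise_scale=cfg.noise_scale, tasks=cfg.tasks):
            vectors.extend(features_from_session(session, cfg))
    return feature_table(vectors)


def simulate_null_table(n_sessions: int, seed: int,
                        config: RunConfig | None = None) -> pd.DataFrame:
    """Feature table in which labels carry no information about features.

    Each row is a single session from a fresh participant whose medication
    response is zero (no suppression, no dyskinesia gain), with the
    medication state drawn at random.  Because the generating parameters
    are then identical pre and post, the label is independent of every
    feature — the chance-level reference for classifier sanity checks.
    """
    import dataclasses

    cfg = config or RunConfig()
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    vectors: list[FeatureVector] = []
    for i, child in enumerate(root.spawn(n_sessions)):
        profile = dataclasses.replace(
            random_profile(rng, f"N{i:04d}", severity_range=cfg.severity_range,
                           suppression_range=(0.0, 0.0)),
            med_dyskinesia_gain=0.0)
        med_state = "pre" if rng.random() < 0.5 else "post"
        session = generate_session(profile, med_state, fs=cfg.fs,
                                   loss_rate=cfg.loss_rate, seed=child,
                                   noise_scale=cfg.noise_scale, tasks=cfg.tasks)
        vectors.extend(features_from_session(session, cfg))
    return feature_table(vectors)


def transport_session(session: SyntheticSession) -> tuple[dict[str, list[codec.SensorFrame]], dict]:
    """Run a session's frames through the wire codec and ingest buffer.

    Frames are encoded into 32-sample payloads per hand (a trailing partial
    payload is never transmitted, as on the device), decoded with ingest
    timestamping at the nominal rate, and batched 128 records at a time.
    Returns the decoded frames per hand and transport counters.
    """
    decoded: dict[str, list[codec.SensorFrame]] = {}
    stats = {"payloads": 0, "records_in": 0, "records_out": 0, "batches": 0}
    for hand, frames in session.frames.items():
        buf = IngestBuffer()
        out: list[codec.SensorFrame] = []
        n_full = len(frames) // codec.PAYLOAD_SAMPLES
        for p in range(n_full):
            chunk = frames[p * codec.PAYLOAD_SAMPLES:(p + 1) * codec.PAYLOAD_SAMPLES]
            body = encode_payload(chunk)
            stats["payloads"] += 1
            stats["records_in"] += len(chunk)
            arrived = decode_payload(body, arrival_time=chunk[-1].t, nominal_fs=session.fs)
            for batch in buf.push(arrived):
                out.extend(batch)
                stats["batches"] += 1
        out.extend(buf.flush())
        stats["records_out"] += len(out)
        decoded[hand] = out
    return decoded, stats


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Artifacts under ``config.output_dir``: per-session CSV exports and
    questionnaires (``sessions/``), the feature table
    (``features/feature_table.csv``), the evaluation report
    (``report/evaluation.json`` and ``.txt``), and ``manifest.json``.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    sessions_dir = out_dir / "sessions"
    features_dir = out_dir / "features"
    report_dir = out_dir / "report"
    for d in (sessions_dir, features_dir, report_dir):
        d.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(config.seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    profiles = [random_profile(profile_rng, f"P{i + 1:02d}",
                               severity_range=config.severity_range,
                               suppression_range=config.suppression_range)
                for i in range(config.n_participants)]

    manifest: dict = {"config": asdict(config), "version": _version(),
                      "participants": [p.participant_id for p in profiles],
                      "transport": {"payloads": 0, "records_in": 0, "records_out": 0, "batches": 0},
                      "sessions": 0}
    vectors: list[FeatureVector] = []
    try:
        for profile, child in zip(profiles, root.spawn(len(profiles))):
            part_dir = sessions_dir / profile.participant_id
            sessions = paired_sessions(
                profile, config.days, seed=int(child.generate_state(1)[0] % 2**31),
                fs=config.fs, loss_rate=config.loss_rate,
                noise_scale=config.noise_scale)
            for session in sessions:
                decoded, stats = transport_session(session)
                for k in stats:
                    manifest["transport"][k] += stats[k]
                session.frames = decoded  # analysis continues on ingested records
                med = 0 if session.med_state == "pre" else 1
                q = Questionnaire(med_intake_bin="0-3 h" if med == 0 else "4+ h")
                write_questionnaire(q, part_dir, session.session_datetime)
                for hand in HANDS:
                    export = from_session(session, hand)
                    write_session(export, part_dir)
                manifest["sessions"] += 1
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"simulate/ingest/export stage failed: {exc}") from exc

    try:
        for part_dir in sorted(sessions_dir.iterdir()):
            for qfile in sorted(part_dir.rglob("questionnaire_*.txt")):
                med = read_questionnaire(qfile).med_state
                stamp = qfile.stem.split("_", 1)[1]
                for hand in HANDS:
                    csv = qfile.parent / f"{hand}_{stamp}.csv"
                    export = read_session(csv, participant_id=part_dir.name)
                    vectors.extend(features_from_export(export, med, config))
    except Exception as exc:
        raise StageError(f"feature stage failed: {exc}") from exc

    table = feature_table(vectors)
    table_path = features_dir / "feature_table.csv"
    write_feature_table(table, table_path)
    manifest["feature_rows"] = int(len(table))

    try:
        dataset = assemble_dataset(table)
        train, test = split_dataset(dataset, config.train_fraction, seed=config.seed)
        report = train_and_evaluate(train, test, model_set=config.model_set,
                                    seed=config.seed,
                                    compute_importance=config.compute_importance)
    except Exception as exc:
        raise StageError(f"classification stage failed: {exc}") from exc
    report.to_json(report_dir / "evaluation.json")
    (report_dir / "evaluation.txt").write_text(report.to_text() + "\n")
    manifest["metrics"] = report.metrics

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _version() -> str:
    from pdglove import __version__
    return __version__
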