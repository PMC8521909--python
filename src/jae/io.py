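"""Disk layout for cohorts: WAV audio, motion CSV, sessions manifest CSV.

One float32 WAV per channel, one motion CSV per session (time_s,
angle_deg), and a long-format manifest with one row per channel so a cohort
round-trips through plain text tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synthetic import AudioRecording, MotionTrace, SubjectSession

__all__ = ["write_cohort", "read_cohort", "read_audio", "read_motion_csv"]

MANIFEST_COLUMNS = ["subject_id", "visit", "group_label", "channel",
                    "audio_path", "motion_path", "fs_audio", "fs_motion"]


def write_audio(path: Path, rec: AudioRecording) -> None:
    wavfile.write(path, int(round(rec.fs)), np.asarray(rec.samples, dtype=np.float32))


def read_audio(path: Path, fs: float | None = None) -> AudioRecording:
    """Read WAV (any PCM subtype, normalized to float) or single-column CSV
    raw audio (fs required)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if fs is None:
            raise ValueError("fs is required for raw CSV audio")
        x = pd.read_csv(path).iloc[:, 0].to_numpy(dtype=np.float32)
        return AudioRecording(samples=x, fs=fs)
    rate, data = wavfile.read(path)
    if data.dtype.kind in "iu":
        data = data.astype(np.float32) / float(np.iinfo(data.dtype).max)
    return AudioRecording(samples=data.astype(np.float32), fs=float(rate))


def write_motion_csv(path: Path, motion: MotionTrace) -> None:
    t = np.arange(len(motion.angle)) / motion.fs
    pd.DataFrame({"time_s": t, "angle_deg": motion.angle}).to_csv(path, index=False)


def read_motion_csv(path: Path) -> MotionTrace:
    df = pd.read_csv(path)
    if len(df) < 2:
        raise ValueError(f"motion trace {path} too short")
    fs = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    return MotionTrace(angle=df["angle_deg"].to_numpy(), fs=round(fs, 6))


def write_cohort(sessions: list[SubjectSession], out_dir: Path) -> Path:
    """Write every session and return the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sess in sessions:
        stem = f"{sess.subject_id}_{sess.visit}"
        motion_path = out_dir / f"{stem}_motion.csv"
        write_motion_csv(motion_path, sess.motion)
        for rec in sess.recordings:
            audio_path = out_dir / f"{stem}_{rec.channel}.wav"
            write_audio(audio_path, rec)
            rows.append((sess.subject_id, sess.visit, sess.group_label,
                         rec.channel, audio_path.name, motion_path.name,
                         rec.fs, sess.motion.fs))
    manifest = out_dir / "sessions.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: Path) -> list[SubjectSession]:
    """Rebuild sessions from a manifest (ground-truth boundaries are not on
    disk; segmentation re-derives cycles from the motion trace)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    sessions = []
    for (sid, visit), grp in df.groupby(["subject_id", "visit"], sort=False):
        motion = read_motion_csv(root / grp["motion_path"].iloc[0])
        recs = []
        for _, row in grp.iterrows():
            rec = read_audio(root / row["audio_path"], fs=row["fs_audio"])
            rec.channel = row["channel"]
            rec.subject_id = sid
            rec.visit = visit
            recs.append(rec)
        sessions.append(SubjectSession(
            subject_id=sid, visit=visit,
            group_label=grp["group_label"].iloc[0],
            recordings=recs, motion=motion,
            true_cycle_boundaries=np.array([], dtype=int)))
    return sessions
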