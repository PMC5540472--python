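"""On-disk layout for recordings.

Each record is a pair of CSV files: ``<id>_skel.csv`` with a time column
followed by 60 joint-coordinate columns (``<joint>_x``, ``<joint>_y``,
``<joint>_z`` in joint-registry order) and ``<id>_eeg.csv`` with a time
column followed by the eight electrode columns.  A ``manifest.csv``
(columns id, label, start, end) indexes the directory.  A continuous
session is written the same way under a single id with global timestamps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    EEG_CHANNELS,
    JOINT_NAMES,
    EEGRecord,
    Record,
    SessionRecord,
    SessionRecording,
    SkeletonSequence,
)

SKEL_COLUMNS = ["t"] + [f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz"]
EEG_COLUMNS = ["t", *EEG_CHANNELS]


def skeleton_to_frame(seq: SkeletonSequence) -> pd.DataFrame:
    flat = seq.data.reshape(seq.n_frames, -1)
    return pd.DataFrame(
        np.column_stack([seq.timestamps, flat]), columns=SKEL_COLUMNS
    )


def frame_to_skeleton(df: pd.DataFrame) -> SkeletonSequence:
    data = df[SKEL_COLUMNS[1:]].to_numpy(dtype=float).reshape(len(df), len(JOINT_NAMES), 3)
    return SkeletonSequence(df["t"].to_numpy(dtype=float), data)


def eeg_to_frame(rec: EEGRecord) -> pd.DataFrame:
    return pd.DataFrame(
        np.column_stack([rec.timestamps, rec.data]), columns=EEG_COLUMNS
    )


def frame_to_eeg(df: pd.DataFrame, rate: float | None = None) -> EEGRecord:
    t = df["t"].to_numpy(dtype=float)
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return EEGRecord(t, df[list(EEG_CHANNELS)].to_numpy(dtype=float), rate)


def write_records(records: list[Record], out_dir: str | Path) -> Path:
    """Write a shuffled dataset: one CSV pair per record plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        rid = f"rec{i:05d}"
        skeleton_to_frame(rec.skeleton).to_csv(out / f"{rid}_skel.csv", index=False)
        eeg_to_frame(rec.eeg).to_csv(out / f"{rid}_eeg.csv", index=False)
        rows.append(
            {
                "id": rid,
                "label": rec.label,
                "start": float(rec.skeleton.timestamps[0]),
                "end": float(rec.skeleton.timestamps[-1]),
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


def read_records(data_dir: str | Path) -> list[Record]:
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    records = []
    for row in manifest.itertuples():
        skel = frame_to_skeleton(pd.read_csv(data_dir / f"{row.id}_skel.csv"))
        eeg = frame_to_eeg(pd.read_csv(data_dir / f"{row.id}_eeg.csv"))
        records.append(Record(skel, eeg, str(row.label)))
    return records


def write_session(session: SessionRecording, out_dir: str | Path) -> Path:
    """Write a continuous session as one CSV pair with global timestamps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skeleton_to_frame(session.skeleton).to_csv(out / "session_skel.csv", index=False)
    eeg_to_frame(session.eeg).to_csv(out / "session_eeg.csv", index=False)
    rows = [
        {"id": f"rec{i:05d}", "label": r.label, "start": r.start, "end": r.end}
        for i, r in enumerate(session.records)
    ]
    pd.DataFrame(rows, columns=["id", "label", "start", "end"]).to_csv(
        out / "manifest.csv", index=False
    )
    return out


def read_session(data_dir: str | Path) -> SessionRecording:
    data_dir = Path(data_dir)
    skeleton = frame_to_skeleton(pd.read_csv(data_dir / "session_skel.csv"))
    eeg = frame_to_eeg(pd.read_csv(data_dir / "session_eeg.csv"))
    manifest = pd.read_csv(data_dir / "manifest.csv")
    records = []
    for row in manifest.itertuples():
        start, end = float(row.start), float(row.end)
        records.append(
            SessionRecord(
                skeleton.slice_time(start, end),
                eeg.slice_time(start, end),
                str(row.label),
                start,
                end,
            )
        )
    return SessionRecording(skeleton, eeg, records)


def is_session_dir(data_dir: str | Path) -> bool:
    return (Path(data_dir) / "session_skel.csv").exists()


def write_feature_table(
    out_dir: str | Path,
    motion: np.ndarray,
    mental: np.ndarray,
    labels,
    motion_scaler=None,
    mental_scaler=None,
) -> Path:
    """Write extracted features as ``features.csv`` (columns ``m000..``,
    ``e000..``, ``label``) plus a ``scalers.json`` sidecar holding the
    fitted [0, 1] scalers, when given."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    motion = np.asarray(motion, dtype=float)
    mental = np.asarray(mental, dtype=float)
    cols = {f"m{i:03d}": motion[:, i] for i in range(motion.shape[1])}
    cols.update({f"e{i:03d}": mental[:, i] for i in range(mental.shape[1])})
    cols["label"] = list(labels)
    pd.DataFrame(cols).to_csv(out / "features.csv", index=False)
    sidecar = {
        "motion_scaler": motion_scaler.to_dict() if motion_scaler else None,
        "mental_scaler": mental_scaler.to_dict() if mental_scaler else None,
    }
    (out / "scalers.json").write_text(json.dumps(sidecar))
    return out


def read_feature_table(data_dir: str | Path):
    """Read ``features.csv`` (+ sidecar) back: (motion, mental, labels,
    scalers) where scalers maps name → fitted scaler or None."""
    import json

    from .scaling import MinMaxScaler

    data_dir = Path(data_dir)
    df = pd.read_csv(data_dir / "features.csv")
    mcols = sorted(c for c in df.columns if c.startswith("m"))
    ecols = sorted(c for c in df.columns if c.startswith("e"))
    sidecar = json.loads((data_dir / "scalers.json").read_text())
    scalers = {
        k: MinMaxScaler.from_dict(v) if v else None
        for k, v in sidecar.items()
    }
    return (
        df[mcols].to_numpy(float),
        df[ecols].to_numpy(float),
        df["label"].to_numpy(),
        scalers,
    )
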