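"""Session interchange format: one directory per session.

``manifest.json``
    subject id, session index, unit ids, window-catalog version.
``trials.csv``
    one row per trial: cue side, first press side, outcome, and the
    event timestamps (ms, integer, session clock).
``spikes.csv``
    unit_id, timestamp_ms; sorted within each unit.

Files are plain text with explicit headers, written deterministically
(trials chronological, spikes sorted), so identical sessions produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .task import Session, SpikeTrain, Trial

SCHEMA_VERSION = "1"
WINDOW_CATALOG_VERSION = "1"

MANIFEST_NAME = "manifest.json"
TRIALS_NAME = "trials.csv"
SPIKES_NAME = "spikes.csv"

_TRIAL_COLUMNS = [
    "trial_index",
    "cue_side",
    "first_press_side",
    "outcome",
    "t_ready_ms",
    "t_cue_ms",
    "t_extend_ms",
    "t_press_ms",
    "t_feedback_ms",
]


def write_session(session: Session, directory: str | Path) -> Path:
    """Write a session bundle; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "window_catalog_version": WINDOW_CATALOG_VERSION,
        "subject_id": session.subject_id,
        "session_index": session.session_index,
        "unit_ids": session.unit_ids,
    }
    (directory / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    trials = sorted(session.trials, key=lambda t: t.t_cue)
    rows = []
    for i, t in enumerate(trials):
        rows.append(
            {
                "trial_index": i,
                "cue_side": t.cue_side,
                "first_press_side": t.first_press_side,
                "outcome": t.outcome,
                "t_ready_ms": int(t.t_ready),
                "t_cue_ms": int(t.t_cue),
                "t_extend_ms": int(t.t_extend),
                "t_press_ms": "" if not np.isfinite(t.t_press) else int(t.t_press),
                "t_feedback_ms": int(t.t_feedback),
            }
        )
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(
        directory / TRIALS_NAME, index=False
    )

    spike_rows = []
    for train in session.spike_trains:
        for ts in np.sort(train.timestamps):
            spike_rows.append({"unit_id": train.unit_id, "timestamp_ms": int(ts)})
    pd.DataFrame(spike_rows, columns=["unit_id", "timestamp_ms"]).to_csv(
        directory / SPIKES_NAME, index=False
    )
    return directory


def read_session(directory: str | Path) -> Session:
    """Read and validate a session bundle.

    Malformed trial rows and unsorted spike timestamps raise ValueError
    messages naming the offending row.
    """
    directory = Path(directory)
    for name in (MANIFEST_NAME, TRIALS_NAME, SPIKES_NAME):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing {name} in {directory}")
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"schema version {manifest.get('schema_version')!r} != {SCHEMA_VERSION!r}"
        )

    trials_df = pd.read_csv(directory / TRIALS_NAME)
    missing = set(_TRIAL_COLUMNS) - set(trials_df.columns)
    if missing:
        raise ValueError(f"trials table missing columns {sorted(missing)}")
    trials = []
    for pos, row in trials_df.iterrows():
        try:
            t_press = row["t_press_ms"]
            t_press = float("nan") if pd.isna(t_press) else float(t_press)
            trials.append(
                Trial(
                    cue_side=str(row["cue_side"]),
                    first_press_side=str(row["first_press_side"]),
                    t_ready=float(row["t_ready_ms"]),
                    t_cue=float(row["t_cue_ms"]),
                    t_extend=float(row["t_extend_ms"]),
                    t_press=t_press,
                    t_feedback=float(row["t_feedback_ms"]),
                    outcome=str(row["outcome"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"trials.csv row {pos + 2}: {exc}") from exc

    spikes_df = pd.read_csv(directory / SPIKES_NAME)
    if list(spikes_df.columns) != ["unit_id", "timestamp_ms"]:
        raise ValueError("spikes table must have columns unit_id, timestamp_ms")
    trains = []
    unit_ids = manifest.get("unit_ids", sorted(spikes_df["unit_id"].unique()))
    for uid in unit_ids:
        sub = spikes_df[spikes_df["unit_id"] == uid]
        ts = sub["timestamp_ms"].to_numpy(dtype=float)
        if ts.size > 1 and np.any(np.diff(ts) < 0):
            bad = int(np.flatnonzero(np.diff(ts) < 0)[0])
            row = int(sub.index[bad + 1]) + 2
            raise ValueError(f"spikes.csv row {row}: unit {uid} timestamps not sorted")
        trains.append(SpikeTrain(unit_id=int(uid), timestamps=ts))
    return Session(
        session_index=int(manifest["session_index"]),
        trials=trials,
        spike_trains=trains,
        subject_id=str(manifest.get("subject_id", "unknown")),
    )


def write_experiment(sessions: Sequence[Session], out_dir: str | Path) -> list[Path]:
    """Write each session to ``out_dir/session_XX``."""
    out_dir = Path(out_dir)
    paths = []
    for s in sessions:
        paths.append(write_session(s, out_dir / f"session_{s.session_index:02d}"))
    return paths


def read_experiment(in_dir: str | Path) -> list[Session]:
    """Read all ``session_*`` bundles under a directory, ordered by index."""
    in_dir = Path(in_dir)
    dirs = sorted(p for p in in_dir.glob("session_*") if p.is_dir())
    if not dirs:
        raise FileNotFoundError(f"no session_* directories under {in_dir}")
    sessions = [read_session(p) for p in dirs]
    return sorted(sessions, key=lambda s: s.session_index)
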