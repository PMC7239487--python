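"""CSV dialects for raw acceleration, breath records and session artifacts.

Raw acceleration files emulate ActiGraph-style raw exports: a header
``timestamp,x,y,z`` with ISO-8601 timestamps and acceleration in g, one
file per wear site.  Breath files carry ``timestamp,vo2_lpm,vco2_lpm,rr``.
Numeric values are written with six decimal places, so a write/read
round-trip is exact to 1e-6.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .records import Participant, RawTriaxialRecording, SyntheticSession, make_breath_table

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


def _timestamps(start: pd.Timestamp, offsets_s: np.ndarray) -> pd.Series:
    t = start + pd.to_timedelta(offsets_s, unit="s")
    return pd.Series(t).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")


def write_raw_csv(recording: RawTriaxialRecording, path: str | Path) -> Path:
    """Write one wear site's raw acceleration as ``timestamp,x,y,z``."""
    path = Path(path)
    if recording.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    offsets = np.arange(recording.n_samples) / recording.sampling_rate
    df = pd.DataFrame(
        {
            "timestamp": _timestamps(recording.start_time, offsets),
            "x": recording.samples[:, 0],
            "y": recording.samples[:, 1],
            "z": recording.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_raw_csv(path: str | Path, site: str = "hip") -> RawTriaxialRecording:
    """Parse a raw acceleration CSV; infers the sampling rate from spacing.

    Unknown extra columns are ignored with a logged notice; missing
    required columns or non-monotone timestamps raise with the offending
    line number (1-based, counting the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["timestamp", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.info("%s: ignoring unknown columns %s", path, extra)
    if len(df) == 0:
        raise ValueError(f"{path}: no samples")
    t = pd.to_datetime(df["timestamp"])
    dt = t.diff().dt.total_seconds().to_numpy()[1:]
    if (dt <= 0).any():
        line = int(np.argmax(dt <= 0)) + 3  # +1 header, +1 first row, +1 offset
        raise ValueError(f"{path}: non-monotone timestamp at line {line}")
    rate = 1.0 / float(np.median(dt)) if len(df) > 1 else 100.0
    return RawTriaxialRecording(
        site=site,
        sampling_rate=round(rate, 6),
        start_time=t.iloc[0],
        samples=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_breath_csv(breaths: pd.DataFrame, start_time: pd.Timestamp,
                     path: str | Path) -> Path:
    path = Path(path)
    out = pd.DataFrame(
        {
            "timestamp": _timestamps(start_time, breaths["time_s"].to_numpy()),
            "vo2_lpm": breaths["vo2_lpm"],
            "vco2_lpm": breaths["vco2_lpm"],
            "rr": breaths.get("rr", np.nan),
        }
    )
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_breath_csv(path: str | Path, origin: pd.Timestamp | None = None) -> pd.DataFrame:
    """Parse a breath CSV into the validated in-memory breath table.

    ``time_s`` is measured from ``origin`` (default: the first breath).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["timestamp", "vo2_lpm", "vco2_lpm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required + ["rr"]]
    if extra:
        logger.info("%s: ignoring unknown columns %s", path, extra)
    t = pd.to_datetime(df["timestamp"])
    if origin is None:
        origin = t.iloc[0]
    time_s = (t - origin).dt.total_seconds().to_numpy()
    dt = np.diff(time_s)
    if (dt <= 0).any():
        line = int(np.argmax(dt <= 0)) + 3
        raise ValueError(f"{path}: non-monotone timestamp at line {line}")
    return make_breath_table(time_s, df["vo2_lpm"], df["vco2_lpm"],
                             df["rr"] if "rr" in df.columns else None)


def write_session(session: SyntheticSession, directory: str | Path) -> dict[str, Path]:
    """Persist one synthetic session as its four-file CSV/JSON set.

    Emits ``<id>_hip.csv``, ``<id>_wrist.csv``, ``<id>_breaths.csv``,
    ``<id>_truth.csv`` and ``<id>_participant.json``; the numeric content
    round-trips through the readers to 1e-6.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = session.participant.id
    if session.hip.n_samples == 0 or session.wrist.n_samples == 0:
        raise ValueError("refusing to write a session with empty recordings")
    paths = {
        "hip": write_raw_csv(session.hip, directory / f"{pid}_hip.csv"),
        "wrist": write_raw_csv(session.wrist, directory / f"{pid}_wrist.csv"),
        "breaths": write_breath_csv(session.breaths, session.start_time,
                                    directory / f"{pid}_breaths.csv"),
    }
    truth = session.truth.copy()
    truth.insert(0, "timestamp",
                 _timestamps(session.start_time, truth["slot_start_s"].to_numpy()))
    truth_path = directory / f"{pid}_truth.csv"
    truth.to_csv(truth_path, index=False, float_format=_FLOAT_FMT)
    paths["truth"] = truth_path

    meta = {
        "id": pid,
        "age": session.participant.age,
        "sex": session.participant.sex,
        "height_m": session.participant.height_m,
        "mass_kg": session.participant.mass_kg,
        "ree_kcal_min": session.ree_kcal_min,
        "start_time": session.start_time.isoformat(),
        "seed": session.seed,
    }
    meta_path = directory / f"{pid}_participant.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    paths["participant"] = meta_path
    return paths


def read_session_files(directory: str | Path, participant_id: str) -> dict:
    """Re-read a written session's file set (inverse of :func:`write_session`)."""
    directory = Path(directory)
    meta = json.loads((directory / f"{participant_id}_participant.json").read_text())
    origin = pd.Timestamp(meta["start_time"])
    return {
        "participant": Participant(
            id=meta["id"], age=meta["age"], sex=meta["sex"],
            height_m=meta["height_m"], mass_kg=meta["mass_kg"],
        ),
        "hip": read_raw_csv(directory / f"{participant_id}_hip.csv", site="hip"),
        "wrist": read_raw_csv(directory / f"{participant_id}_wrist.csv", site="wrist"),
        "breaths": read_breath_csv(directory / f"{participant_id}_breaths.csv",
                                   origin=origin),
        "truth": pd.read_csv(directory / f"{participant_id}_truth.csv"),
        "meta": meta,
    }


def write_cohort_manifest(participants, groups: dict[str, str],
                          path: str | Path) -> Path:
    """One row per participant: id, age, sex, height_m, mass_kg, group."""
    rows = [
        {
            "id": p.id, "age": p.age, "sex": p.sex,
            "height_m": p.height_m, "mass_kg": p.mass_kg,
            "group": groups[p.id],
        }
        for p in participants
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
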