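"""CSV dialects for traces, frame picks, jump records and reports.

All files are plain CSV.  Force traces carry their metadata (identifiers,
sampling rate, body mass) as ``# key = value`` comment lines above the
header so a single file is self-describing.
"""

from __future__ import annotations

import decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .forceplate import ForceTrace
from .video import FramePick

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_records_csv",
    "read_records_csv",
    "write_frame_picks_csv",
    "read_frame_picks_csv",
    "round_half_up",
]

RECORD_COLUMNS = ["participant_id", "sex", "trial_id",
                  "jh_tia_cm", "jh_tov_cm", "jh_mj_cm"]
PICK_COLUMNS = ["participant_id", "trial_id", "observer_id",
                "first_flight_frame", "first_contact_frame", "fps"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the spreadsheet convention).

    Report tables use half-up rounding (1.15 -> 1.2 at one decimal), not
    the banker's rounding of Python's built-in ``round``.
    """
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def write_trace_csv(trace: ForceTrace, path: str | Path,
                    body_mass: float | None = None) -> None:
    """Write one force trace with its metadata comment header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# participant_id = {trace.participant_id}\n")
        fh.write(f"# trial_id = {trace.trial_id}\n")
        fh.write(f"# sample_rate_hz = {trace.sample_rate!r}\n")
        if body_mass is not None:
            fh.write(f"# body_mass_kg = {body_mass!r}\n")
        fh.write("time_s,force_n\n")
        t = trace.time
        for ti, fi in zip(t, trace.force):
            fh.write(f"{ti:.6f},{fi:.6f}\n")


def read_trace_csv(path: str | Path) -> ForceTrace:
    """Read a force trace written by :func:`write_trace_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
    if "sample_rate_hz" not in meta:
        raise ValueError(f"{path}: missing '# sample_rate_hz = ...' header")
    df = pd.read_csv(path, comment="#")
    if "force_n" not in df.columns:
        raise ValueError(f"{path}: missing force_n column")
    return ForceTrace(
        force=df["force_n"].to_numpy(dtype=float),
        sample_rate=float(meta["sample_rate_hz"]),
        participant_id=meta.get("participant_id", ""),
        trial_id=meta.get("trial_id", ""),
    )


def write_records_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write a jump-record table (heights in cm, full precision)."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")
    records[RECORD_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Read a jump-record table, validating its schema."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["participant_id", "trial_id"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (participant, trial) keys")
    return df


def write_frame_picks_csv(picks: list[FramePick], path: str | Path) -> None:
    rows = [{
        "participant_id": p.participant_id, "trial_id": p.trial_id,
        "observer_id": p.observer_id,
        "first_flight_frame": p.first_flight_frame,
        "first_contact_frame": p.first_contact_frame, "fps": p.fps,
    } for p in picks]
    pd.DataFrame(rows, columns=PICK_COLUMNS).to_csv(path, index=False)


def read_frame_picks_csv(path: str | Path) -> list[FramePick]:
    df = pd.read_csv(path)
    missing = [c for c in PICK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        FramePick(
            first_flight_frame=int(r.first_flight_frame),
            first_contact_frame=int(r.first_contact_frame),
            fps=float(r.fps),
            observer_id=str(r.observer_id),
            participant_id=str(r.participant_id),
            trial_id=str(r.trial_id),
        )
        for r in df.itertuples()
    ]
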