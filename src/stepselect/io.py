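"""Telemetry and table readers/writers.

Telemetry CSV contract: columns ``individual_id, timestamp, x, y`` with
ISO-8601 UTC timestamps and planar-metre coordinates at a nominal 5-minute
fix schedule. Internal time is seconds since each track's first fix.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .simulate import Track

__all__ = ["read_telemetry", "write_telemetry", "read_case_control", "write_case_control"]

TELEMETRY_COLUMNS = ["individual_id", "timestamp", "x", "y"]
EPOCH = pd.Timestamp("2016-01-01T00:00:00Z")


def read_telemetry(path: str | Path) -> list[Track]:
    """Parse a telemetry CSV into per-individual tracks, sorted by time."""
    df = pd.read_csv(path)
    missing = set(TELEMETRY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        bad = None
        for i, v in enumerate(df["timestamp"]):
            try:
                pd.Timestamp(v)
            except (ValueError, TypeError):
                bad = i
                break
        raise FormatError(f"{path}: unparseable timestamp at data row {bad}")
    df = df.assign(_ts=ts)
    tracks = []
    for ind, g in df.groupby("individual_id", sort=True):
        dup = g["_ts"].duplicated()
        if dup.any():
            row = g.index[dup][0]
            raise FormatError(
                f"{path}: duplicate timestamp for individual {ind!r} at data row {row}"
            )
        if not g["_ts"].is_monotonic_increasing:
            warnings.warn(
                f"{path}: fixes for {ind!r} not time-ordered; sorting", stacklevel=2
            )
            g = g.sort_values("_ts")
        t = (g["_ts"] - g["_ts"].iloc[0]).dt.total_seconds().to_numpy()
        tracks.append(
            Track(
                individual_id=str(ind),
                t=t,
                x=g["x"].to_numpy(dtype=float),
                y=g["y"].to_numpy(dtype=float),
            )
        )
    return tracks


def write_telemetry(tracks: list[Track], path: str | Path, t0: pd.Timestamp = EPOCH) -> None:
    frames = []
    for tr in tracks:
        stamps = t0 + pd.to_timedelta(tr.t, unit="s")
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": tr.individual_id,
                    "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "x": tr.x,
                    "y": tr.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


CASE_CONTROL_LEAD = [
    "case",
    "stratum_id",
    "individual_id",
    "ln_step_length",
    "cos_turn_angle",
]


def write_case_control(table: pd.DataFrame, path: str | Path) -> None:
    cov = [c for c in table.columns if c.startswith(("dist_", "dens_", "lag_"))]
    extra = [c for c in table.columns if c not in CASE_CONTROL_LEAD + cov]
    table[CASE_CONTROL_LEAD + cov + extra].to_csv(path, index=False)


def read_case_control(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CASE_CONTROL_LEAD) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df
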