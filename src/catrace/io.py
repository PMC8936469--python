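"""Delimited-text I/O for traces, event tables, and metrics tables.

Trace files are plain CSV: one header row of unique ROI identifiers, one
column per ROI, one row per frame.  Writing and re-reading a matrix
round-trips exactly on the text representation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trace_model import SessionInfo, TraceMatrix

__all__ = [
    "read_traces",
    "write_traces",
    "read_events",
    "write_events",
    "read_table",
    "write_table",
]


def read_traces(
    path, sampling_rate: float, session: SessionInfo | None = None
) -> TraceMatrix:
    """Read a frames × ROIs CSV matrix into a :class:`TraceMatrix`.

    Ragged rows, non-numeric cells, and duplicate ROI ids are rejected
    with the offending location named.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    ids = [c.strip() for c in header.split(",")]
    seen: set[str] = set()
    for c in ids:
        if c in seen:
            raise ValueError(f"duplicate ROI id {c!r} in header of {path}")
        seen.add(c)
    try:
        df = pd.read_csv(
            path,
            header=0,
            names=ids,
            skipinitialspace=True,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed trace file {path}: {err}") from err
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        # reparse as text purely to name the offending cell
        raw = pd.read_csv(path, header=0, names=ids, dtype=str)
        for col in ids:
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            bad |= raw[col].isna()
            if bad.any():
                frame = int(np.flatnonzero(bad)[0])
                cell = raw[col].iloc[frame]
                raise ValueError(
                    f"non-numeric cell {cell!r} at frame row {frame} "
                    f"(file row {frame + 2}), column {col!r} of {path}"
                )
        raise ValueError(f"non-numeric data in trace file {path}")
    if df.isna().to_numpy().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        raise ValueError(
            f"missing value at frame row {rows[0]} (file row {rows[0] + 2}), "
            f"column {ids[cols[0]]!r} of {path}"
        )
    return TraceMatrix(
        values=df.to_numpy(dtype=np.float64).T,
        sampling_rate=sampling_rate,
        roi_ids=tuple(ids),
        session=session,
    )


def write_traces(trace_matrix: TraceMatrix, path) -> None:
    """Write a matrix as frames × ROIs CSV with an ROI-id header."""
    df = pd.DataFrame(trace_matrix.values.T, columns=list(trace_matrix.roi_ids))
    df.to_csv(path, index=False)


EVENT_COLUMNS = [
    "roi_id",
    "peak_frame",
    "peak_time_s",
    "amplitude",
    "pass_level",
    "run_start",
    "run_end",
]


def write_events(events_df: pd.DataFrame, path) -> None:
    """Write an event table (one row per detected transient)."""
    missing = [c for c in EVENT_COLUMNS if c not in events_df.columns]
    if missing:
        raise ValueError(f"event table is missing columns {missing}")
    events_df.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file {path} is missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
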