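"""CSV reading/writing for paired resonator traces.

Dialect: comma-delimited, header row ``time_s,<channel>_<label>,...``
with time in seconds (strictly increasing, uniform), frequency columns in
Hz and dissipation columns in units of 1e-6. Missing values are rejected
outright — no imputation — and non-uniform time grids are rejected naming
the offending row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_model import ChannelKind, PairedRecord, ResonatorTrace
from .synthetic import SimTruth

__all__ = ["read_traces", "write_traces", "infer_sample_rate"]

_REL_TOL = 1e-6  # uniformity tolerance on the time step


class TraceFileError(ValueError):
    """Malformed trace file (header, time grid, or cell contents)."""


def _channel_kind(column: str) -> ChannelKind:
    prefix = column.split("_", 1)[0]
    if prefix not in ("frequency", "dissipation"):
        raise TraceFileError(
            f"column {column!r} must be named <channel>_<label> with channel "
            f"'frequency' or 'dissipation'"
        )
    return prefix  # type: ignore[return-value]


def infer_sample_rate(time_s: np.ndarray) -> float:
    """Sample rate from a uniform, strictly increasing time column.

    Raises :class:`TraceFileError` naming the first offending row if the
    grid is non-uniform beyond 1e-6 relative tolerance.
    """
    t = np.asarray(time_s, dtype=float)
    if t.size < 2:
        raise TraceFileError("need at least 2 samples to infer a sample rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise TraceFileError(f"time column not strictly increasing at row {row}")
    step = float(np.median(dt))
    bad = np.abs(dt - step) > _REL_TOL * step
    if np.any(bad):
        row = int(np.flatnonzero(bad)[0]) + 1
        raise TraceFileError(
            f"non-uniform sampling at row {row}: step {dt[bad][0]:g}s vs {step:g}s"
        )
    return 1.0 / step


def read_traces(
    path: str | Path,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[PairedRecord]:
    """Read one or more sensor/reference pairs from a dialect CSV.

    Parameters
    ----------
    path
        CSV file with a ``time_s`` column.
    pairs
        Explicit (sensor_column, reference_column) mappings. When omitted,
        columns are auto-paired per channel prefix: ``<channel>_sensor*``
        with the matching ``<channel>_reference*`` (same suffix).
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise TraceFileError(f"{path}: missing required 'time_s' column")
    if df.shape[0] < 2:
        raise TraceFileError(f"{path}: need at least 2 rows")
    na = df.isna()
    if na.to_numpy().any():
        row = int(na.any(axis=1).idxmax()) + 1
        raise TraceFileError(f"{path}: missing value at row {row}")
    rate = infer_sample_rate(df["time_s"].to_numpy())

    if pairs is None:
        pairs = []
        for col in df.columns:
            if col.split("_", 1)[0] in ("frequency", "dissipation") and "_sensor" in col:
                ref = col.replace("_sensor", "_reference", 1)
                if ref in df.columns:
                    pairs.append((col, ref))
        if not pairs:
            raise TraceFileError(
                f"{path}: no sensor/reference column pairs found; pass an "
                f"explicit mapping"
            )

    records = []
    for sensor_col, ref_col in pairs:
        for c in (sensor_col, ref_col):
            if c not in df.columns:
                raise TraceFileError(f"{path}: no column named {c!r}")
        kind = _channel_kind(sensor_col)
        if kind != _channel_kind(ref_col):
            raise TraceFileError(
                f"{path}: cannot pair {sensor_col!r} with {ref_col!r}: "
                f"different channels"
            )
        records.append(
            PairedRecord(
                sensor=ResonatorTrace(df[sensor_col].to_numpy(float), rate, kind, sensor_col),
                reference=ResonatorTrace(df[ref_col].to_numpy(float), rate, kind, ref_col),
            )
        )
    return records


def write_traces(
    records: Sequence[PairedRecord],
    path: str | Path,
    truth: Mapping[str, SimTruth] | SimTruth | None = None,
) -> None:
    """Write paired records (and optionally ground-truth components) to a
    dialect CSV.

    With ``truth`` given, per-component columns (binding/drift/sawtooth/
    noise per channel) are appended; they sum exactly to the trace
    columns. An empty record list yields a header-only file.
    """
    cols: dict[str, np.ndarray] = {}
    if records:
        n = len(records[0])
        rate = records[0].sample_rate
        for rec in records:
            if len(rec) != n or not np.isclose(rec.sample_rate, rate):
                raise ValueError("all records in one file must share a time grid")
        cols["time_s"] = np.arange(n) / rate
        for i, rec in enumerate(records):
            kind = rec.channel_kind
            s_label = rec.sensor.label or (f"{kind}_sensor{i}" if len(records) > 1 else f"{kind}_sensor")
            r_label = rec.reference.label or (f"{kind}_reference{i}" if len(records) > 1 else f"{kind}_reference")
            if not s_label.startswith(kind):
                s_label = f"{kind}_{s_label}"
            if not r_label.startswith(kind):
                r_label = f"{kind}_{r_label}"
            cols[s_label] = rec.sensor.values
            cols[r_label] = rec.reference.values
    else:
        cols["time_s"] = np.empty(0)

    if truth is not None and records:
        items = truth.items() if isinstance(truth, Mapping) else [("truth", truth)]
        for name, tr in items:
            for comp in ("binding", "drift", "sawtooth", "noise"):
                cols[f"{name}_{comp}_sensor"] = getattr(tr, f"{comp}_sensor")
                cols[f"{name}_{comp}_reference"] = getattr(tr, f"{comp}_reference")
    pd.DataFrame(cols).to_csv(path, index=False)
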