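"""Readers and writers for the minute-epoch and day-epoch CSV dialects.

Two device streams are supported:

* "AG" minute files — ``subject_id,timestamp,vm_counts,steps`` — one row per
  device-minute with vector-magnitude counts and step counts.
* "OM" minute files — ``subject_id,timestamp,mets`` — one row per
  device-minute with estimated METs.
* "OM" daily files — ``subject_id,date,steps`` — one row per subject-day
  with the day-epoch step total.

Timestamps are naive local time at minute resolution (seconds must be zero);
both devices are assumed to share a clock.  A "day" is the calendar date of
the timestamp.  Readers return :class:`pandas.DataFrame` objects sorted by
``(subject_id, timestamp)`` and enforce uniqueness of the key; writers emit
RFC 4180-style CSV with exactly the headers above, so that
``read(write(df)) == df`` for valid frames.

Proprietary vendor export formats (.agd/.gt3x, Omron binaries) are out of
scope; converting them to these dialects is a documented extension point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AG_MINUTE_COLUMNS = ["subject_id", "timestamp", "vm_counts", "steps"]
OM_MINUTE_COLUMNS = ["subject_id", "timestamp", "mets"]
OM_DAILY_COLUMNS = ["subject_id", "date", "steps"]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"
DATE_FORMAT = "%Y-%m-%d"


class FormatError(ValueError):
    """A file violates the expected CSV dialect."""


def _load_table(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; header must be {columns}")
    return df[columns]


def _parse_timestamps(df: pd.DataFrame, column: str, path) -> pd.Series:
    ts = pd.to_datetime(df[column], format="ISO8601", errors="coerce")
    bad = ts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise FormatError(f"{path}: unparseable {column} at line {row}: {df[column].iloc[row - 2]!r}")
    return ts


def _check_minute_aligned(ts: pd.Series, path) -> None:
    off = (ts.dt.second != 0) | (ts.dt.microsecond != 0) | (ts.dt.nanosecond != 0)
    if off.any():
        row = int(np.flatnonzero(off.to_numpy())[0]) + 2
        raise FormatError(f"{path}: timestamp not minute-aligned at line {row}")


def _check_nonnegative(df: pd.DataFrame, column: str, path) -> None:
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = vals.isna() | (vals < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"{path}: invalid {column} at line {row}: {df[column].iloc[row - 2]!r} (must be a nonnegative number)"
        )


def _check_unique(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        first = df.loc[dup, keys].iloc[0]
        raise FormatError(f"{path}: duplicate key {tuple(first)} on {keys}")


def read_ag_minutes(path) -> pd.DataFrame:
    """Read an AG minute-epoch CSV.

    Returns a frame with columns ``subject_id`` (str), ``timestamp``
    (datetime64, minute-aligned), ``vm_counts`` (int), ``steps`` (int),
    sorted by ``(subject_id, timestamp)``.

    Raises
    ------
    FormatError
        On a missing column, unparseable timestamp, negative value or a
        duplicated ``(subject_id, timestamp)`` key; the message names the
        offending line or key.
    """
    df = _load_table(path, AG_MINUTE_COLUMNS)
    df["timestamp"] = _parse_timestamps(df, "timestamp", path)
    _check_minute_aligned(df["timestamp"], path)
    for col in ("vm_counts", "steps"):
        _check_nonnegative(df, col, path)
        df[col] = df[col].astype(np.int64)
    _check_unique(df, ["subject_id", "timestamp"], path)
    return df.sort_values(["subject_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def read_om_minutes(path) -> pd.DataFrame:
    """Read an OM minute-epoch CSV (``subject_id,timestamp,mets``)."""
    df = _load_table(path, OM_MINUTE_COLUMNS)
    df["timestamp"] = _parse_timestamps(df, "timestamp", path)
    _check_minute_aligned(df["timestamp"], path)
    _check_nonnegative(df, "mets", path)
    df["mets"] = df["mets"].astype(float)
    _check_unique(df, ["subject_id", "timestamp"], path)
    return df.sort_values(["subject_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def read_om_daily(path) -> pd.DataFrame:
    """Read an OM day-epoch step CSV (``subject_id,date,steps``)."""
    df = _load_table(path, OM_DAILY_COLUMNS)
    dates = pd.to_datetime(df["date"], format=DATE_FORMAT, errors="coerce")
    bad = dates.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(f"{path}: unparseable date at line {row}: {df['date'].iloc[row - 2]!r}")
    df["date"] = dates
    _check_nonnegative(df, "steps", path)
    df["steps"] = df["steps"].astype(np.int64)
    _check_unique(df, ["subject_id", "date"], path)
    return df.sort_values(["subject_id", "date"], kind="mergesort").reset_index(drop=True)


def write_ag_minutes(df: pd.DataFrame, path) -> None:
    out = df[AG_MINUTE_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False, lineterminator="\r\n")


def write_om_minutes(df: pd.DataFrame, path) -> None:
    out = df[OM_MINUTE_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False, lineterminator="\r\n")


def write_om_daily(df: pd.DataFrame, path) -> None:
    out = df[OM_DAILY_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime(DATE_FORMAT)
    out.to_csv(path, index=False, lineterminator="\r\n")
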