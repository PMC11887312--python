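"""Merge paired minute streams and aggregate to participant-days.

The two outcomes are handled asymmetrically, mirroring how day-epoch step
totals and minute-epoch intensity data must be treated:

* steps — the AG daily total sums the steps of ALL AG minutes of the date,
  worn and non-worn alike (the day-epoch OM total cannot be masked, so both
  devices retain non-wear steps to stay comparable);
* MVPA — minutes are classified only when present in BOTH minute streams
  (inner join on subject and timestamp) and worn; the AG wear mask is
  propagated to the OM stream (shared belt).

Thresholds are inclusive on ">=" and exclusive on "<" exactly as stated:
MVPA at METs >= 3.0 (OM) and vm_counts >= 2690 (AG); a valid day has
wear >= 600 minutes and daily steps in [100, 50000) on both devices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("accelagree")

__all__ = [
    "CutPoints",
    "ValidDayRule",
    "MergeTally",
    "merge_minutes",
    "build_daily",
    "filter_valid_days",
    "DAILY_COLUMNS",
]

DAILY_COLUMNS = [
    "subject_id",
    "date",
    "ag_steps",
    "om_steps",
    "ag_mvpa_min",
    "om_mvpa_min",
    "wear_min",
    "valid",
]


@dataclass(frozen=True)
class CutPoints:
    """Inclusive MVPA thresholds per device channel."""

    om_mvpa_mets: float = 3.0
    ag_mvpa_cpm: int = 2690

    def __post_init__(self) -> None:
        if self.om_mvpa_mets <= 0 or self.ag_mvpa_cpm <= 0:
            raise ValueError("cut-points must be positive")


@dataclass(frozen=True)
class ValidDayRule:
    """Wear-time and step-plausibility bounds defining an analysable day."""

    min_wear_minutes: int = 600
    min_steps: int = 100  # inclusive
    max_steps: int = 50_000  # exclusive

    def __post_init__(self) -> None:
        if self.min_wear_minutes <= 0:
            raise ValueError("min_wear_minutes must be positive")
        if not self.min_steps < self.max_steps:
            raise ValueError("min_steps must be below max_steps")


@dataclass(frozen=True)
class MergeTally:
    """Minutes dropped by the inner join, per side."""

    om_only: int
    ag_only: int


def merge_minutes(om_minutes: pd.DataFrame, ag_minutes: pd.DataFrame) -> tuple[pd.DataFrame, MergeTally]:
    """Inner-join the OM and AG minute streams on (subject_id, timestamp).

    Minutes present in only one stream are dropped and counted in the
    returned :class:`MergeTally`.
    """
    merged = om_minutes.merge(ag_minutes, on=["subject_id", "timestamp"], how="outer", indicator=True)
    tally = MergeTally(
        om_only=int((merged["_merge"] == "left_only").sum()),
        ag_only=int((merged["_merge"] == "right_only").sum()),
    )
    joined = (
        merged[merged["_merge"] == "both"]
        .drop(columns="_merge")
        .sort_values(["subject_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    joined["vm_counts"] = joined["vm_counts"].astype(np.int64)
    joined["steps"] = joined["steps"].astype(np.int64)
    if tally.om_only or tally.ag_only:
        logger.info(
            "merge dropped %d OM-only and %d AG-only minutes", tally.om_only, tally.ag_only
        )
    return joined, tally


def build_daily(
    joined: pd.DataFrame,
    ag_minutes: pd.DataFrame,
    wear_mask: np.ndarray,
    om_daily: pd.DataFrame,
    cutpoints: CutPoints = CutPoints(),
    rule: ValidDayRule = ValidDayRule(),
) -> pd.DataFrame:
    """Aggregate to one row per participant-day.

    Parameters
    ----------
    joined
        Inner-joined minute table from :func:`merge_minutes` (used for MVPA).
    ag_minutes, wear_mask
        The full AG minute stream (used for daily steps and wear time) and
        its aligned wear mask.
    om_daily
        Day-epoch OM step records.  A date with minute data but no OM step
        record is emitted with ``om_steps`` missing and ``valid=False``.

    Returns a frame with columns ``subject_id, date, ag_steps, om_steps,
    ag_mvpa_min, om_mvpa_min, wear_min, valid``; dates with zero AG minutes
    are not emitted.
    """
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if len(wear_mask) != len(ag_minutes):
        raise ValueError("wear_mask must align with ag_minutes")

    ag = ag_minutes[["subject_id", "timestamp", "steps"]].copy()
    ag["wear"] = wear_mask
    ag["date"] = ag["timestamp"].dt.normalize()
    per_day = ag.groupby(["subject_id", "date"], as_index=False).agg(
        ag_steps=("steps", "sum"), wear_min=("wear", "sum")
    )

    j = joined.merge(
        ag_minutes[["subject_id", "timestamp"]].assign(wear=wear_mask),
        on=["subject_id", "timestamp"],
        how="left",
    )
    j["wear"] = j["wear"].fillna(False).astype(bool)
    j["date"] = j["timestamp"].dt.normalize()
    j["om_mvpa"] = j["wear"] & (j["mets"] >= cutpoints.om_mvpa_mets)
    j["ag_mvpa"] = j["wear"] & (j["vm_counts"] >= cutpoints.ag_mvpa_cpm)
    mvpa = j.groupby(["subject_id", "date"], as_index=False).agg(
        om_mvpa_min=("om_mvpa", "sum"), ag_mvpa_min=("ag_mvpa", "sum")
    )

    daily = per_day.merge(mvpa, on=["subject_id", "date"], how="left")
    daily[["om_mvpa_min", "ag_mvpa_min"]] = daily[["om_mvpa_min", "ag_mvpa_min"]].fillna(0)

    om = om_daily.rename(columns={"steps": "om_steps"})
    om = om.assign(date=pd.to_datetime(om["date"]))
    daily = daily.merge(om[["subject_id", "date", "om_steps"]], on=["subject_id", "date"], how="left")
    missing = daily["om_steps"].isna()
    if missing.any():
        for _, row in daily.loc[missing, ["subject_id", "date"]].iterrows():
            logger.warning(
                "no OM daily step record for %s %s; day marked invalid",
                row["subject_id"],
                row["date"].date(),
            )

    daily["valid"] = _valid(daily, rule)
    for col in ("ag_steps", "ag_mvpa_min", "om_mvpa_min", "wear_min"):
        daily[col] = daily[col].astype(np.int64)
    daily["om_steps"] = daily["om_steps"].astype("Int64")
    return daily[DAILY_COLUMNS].sort_values(["subject_id", "date"], kind="mergesort").reset_index(drop=True)


def _valid(daily: pd.DataFrame, rule: ValidDayRule) -> pd.Series:
    ok_wear = daily["wear_min"] >= rule.min_wear_minutes
    ok_ag = (daily["ag_steps"] >= rule.min_steps) & (daily["ag_steps"] < rule.max_steps)
    om = daily["om_steps"]
    ok_om = om.notna() & (om >= rule.min_steps) & (om < rule.max_steps)
    return (ok_wear & ok_ag & ok_om).astype(bool)


def filter_valid_days(daily: pd.DataFrame, rule: ValidDayRule = ValidDayRule()) -> pd.DataFrame:
    """Return the valid subset of a daily-summary table under ``rule``.

    Validity is recomputed from the rule, so a table built under one rule can
    be re-filtered under another.
    """
    keep = _valid(daily, rule)
    out = daily[keep].copy()
    out["valid"] = True
    return out.reset_index(drop=True)
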