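"""Non-wear detection on minute-epoch count streams.

A minute is classified non-worn when it lies inside a maximal interval of
zero vector-magnitude counts of length >= ``window_minutes``, where short
nonzero interruptions (spikes) of at most ``spike_tolerance_minutes`` are
absorbed into the interval provided they are flanked on both sides by at
least ``flank_minutes`` of consecutive zeros.  The 90/2/30 defaults follow a
widely used heuristic for count data; all three parameters are configurable
and should be recorded alongside any output they produced.

Detection runs on vector-magnitude counts so that the wear channel matches
the intensity-classification channel.  Minutes absent from a stream
contribute neither wear nor non-wear time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WearParams", "detect_nonwear", "detect_nonwear_frame", "nonwear_step_diagnostics"]


@dataclass(frozen=True)
class WearParams:
    """Parameters of the zero-run non-wear heuristic."""

    window_minutes: int = 90
    spike_tolerance_minutes: int = 2
    flank_minutes: int = 30

    def __post_init__(self) -> None:
        if self.window_minutes <= 0 or self.spike_tolerance_minutes <= 0 or self.flank_minutes <= 0:
            raise ValueError("all WearParams fields must be positive")
        if self.flank_minutes > self.window_minutes:
            raise ValueError("flank_minutes must not exceed window_minutes")


def _runs(values: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length encode ``values == 0`` as (is_zero, start, length) triples."""
    if len(values) == 0:
        return []
    iszero = values == 0
    change = np.flatnonzero(iszero[1:] != iszero[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    return [(bool(iszero[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_nonwear(counts, params: WearParams = WearParams()) -> np.ndarray:
    """Classify a single contiguous stream of per-minute counts.

    Parameters
    ----------
    counts : array-like of nonnegative int
        Vector-magnitude counts of one contiguous subject stream, in time
        order.
    params : WearParams
        Window / spike-tolerance / flank lengths.

    Returns
    -------
    numpy.ndarray of bool
        Wear mask aligned to ``counts``: ``True`` = worn, ``False`` =
        non-worn.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    worn = np.ones(len(counts), dtype=bool)
    runs = _runs(counts)

    # A nonzero run is absorbable when it is short enough and both
    # neighbouring zero runs are at least flank_minutes long.
    def absorbable(i: int) -> bool:
        is_zero, _, length = runs[i]
        if is_zero or length > params.spike_tolerance_minutes:
            return False
        if i == 0 or i == len(runs) - 1:
            return False
        return runs[i - 1][2] >= params.flank_minutes and runs[i + 1][2] >= params.flank_minutes

    i = 0
    while i < len(runs):
        if not runs[i][0]:
            i += 1
            continue
        # grow a block: zero run, then (absorbable spike, zero run)*
        j = i
        while j + 2 < len(runs) and absorbable(j + 1):
            j += 2
        start = runs[i][1]
        end = runs[j][1] + runs[j][2]
        if end - start >= params.window_minutes:
            worn[start:end] = False
        i = j + 1
    return worn


def detect_nonwear_frame(ag_minutes: pd.DataFrame, params: WearParams = WearParams()) -> np.ndarray:
    """Wear mask for a multi-subject AG minute frame.

    The frame must be sorted by ``(subject_id, timestamp)``; an unsorted
    frame raises ``ValueError``.  Within a subject, runs of consecutive
    minutes (timestamp gaps of exactly one minute) are treated as separate
    contiguous streams, so zero runs never bridge a recording gap.
    """
    subj = ag_minutes["subject_id"].to_numpy()
    ts = ag_minutes["timestamp"].to_numpy()
    counts = ag_minutes["vm_counts"].to_numpy()
    n = len(ag_minutes)
    mask = np.ones(n, dtype=bool)
    if n == 0:
        return mask
    same_subject = subj[1:] == subj[:-1]
    if np.any(same_subject & (ts[1:] <= ts[:-1])):
        raise ValueError("ag_minutes must be sorted by (subject_id, timestamp)")
    one_min = np.timedelta64(60, "s")
    contiguous = same_subject & ((ts[1:] - ts[:-1]) == one_min)
    breaks = np.flatnonzero(~contiguous) + 1
    for s, e in zip(np.concatenate(([0], breaks)), np.concatenate((breaks, [n]))):
        mask[s:e] = detect_nonwear(counts[s:e], params)
    return mask


def nonwear_step_diagnostics(ag_minutes, wear_mask) -> tuple[int, float]:
    """Summarise AG step counts over the non-worn minutes.

    Returns ``(max steps/min during non-wear, proportion of non-worn minutes
    with zero steps)``.  With no non-worn minutes the convention ``(0, 1.0)``
    is returned and a warning is issued.
    """
    if isinstance(ag_minutes, pd.DataFrame):
        steps = ag_minutes["steps"].to_numpy()
    else:
        steps = np.asarray(ag_minutes)
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if len(steps) != len(wear_mask):
        raise ValueError(f"mask length {len(wear_mask)} does not match stream length {len(steps)}")
    nonworn = steps[~wear_mask]
    if len(nonworn) == 0:
        warnings.warn("no non-worn minutes; returning (0, 1.0) by convention", stacklevel=2)
        return 0, 1.0
    return int(nonworn.max()), float(np.mean(nonworn == 0))
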