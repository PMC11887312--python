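"""Synthetic paired-device activity data with known ground truth.

Two fidelity levels are generated from one :class:`SimConfig`:

* :func:`simulate_paired_differences` — daily paired differences drawn
  directly from the random-intercept difference model

      d_ij = delta0 + delta1 * (m_ij - reference_m) + b_i + e_ij,
      b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2),

  where the daily level m_ij has its own between/within-subject normal
  decomposition.  This is the oracle input for the agreement statistics.

* :func:`simulate_minute_streams` — full minute-epoch streams for both
  devices on a shared timestamp grid, produced by a Markov chain over three
  activity states (sedentary / light / moderate-locomotive), with scheduled
  non-wear bouts injected as zero-count, zero-step AG minutes (the OM
  minutes remain present, matching the shared-belt design) and per-day
  ground-truth summaries returned alongside.  Device bias is injected
  deterministically: the OM daily step total is the AG total plus a fixed
  discrepancy, and a fixed number of worn sub-moderate minutes per day have
  their METs raised to the moderate threshold so that only the OM classifies
  them as MVPA.

The free-living activity dynamics (states, transition matrix, per-state
count/step/MET levels) are artifact inventions chosen only to produce
plausible daily magnitudes; no published generative model underlies them.

Randomness contract: a single integer seed fully determines all output.
Subject k consumes the k-th child of ``numpy.random.SeedSequence(seed)``,
so per-subject streams do not depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import epoch_io

__all__ = [
    "SimConfig",
    "ConfigError",
    "simulate_paired_differences",
    "simulate_minute_streams",
    "make_reference_dataset",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["subject_id", "date", "m_steps", "d_steps", "m_mvpa", "d_mvpa", "wear_min"]

_DEFAULT_TRANSITION = (
    (0.90, 0.08, 0.02),
    (0.15, 0.75, 0.10),
    (0.05, 0.20, 0.75),
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of the paired-device generator.

    The difference-model block (``delta0`` ... ``sigma_m_within``,
    ``reference_m``) drives :func:`simulate_paired_differences`; the
    schedule/state block drives :func:`simulate_minute_streams`.  Proportional
    bias is injected around ``reference_m`` (default: ``mu_m``) so that
    ``delta0`` stays interpretable as the mean difference at that level.
    """

    n_subjects: int = 129
    days_per_subject: int = 7
    seed: int = 0

    # difference model (single generic daily outcome)
    delta0: float = 23.0
    delta1: float = 0.0
    sigma_b: float = 15.0
    sigma_w: float = 14.0
    mu_m: float = 57.0
    sigma_m_between: float = 20.0
    sigma_m_within: float = 10.0
    reference_m: float | None = None

    # wear schedule
    start_date: str = "2024-03-04"
    wake_start_hour: int = 7
    wake_minutes: int = 960
    nonwear_bouts_per_day: int = 1
    nonwear_bout_minutes: int = 120
    nonwear_bout_offsets: tuple[int, ...] | None = None  # minutes after wake start

    # activity-state process (sedentary, light, moderate-locomotive)
    state_transition: tuple[tuple[float, float, float], ...] = _DEFAULT_TRANSITION
    steps_per_state: tuple[float, float, float] = (0.0, 30.0, 110.0)
    counts_per_state: tuple[float, float, float] = (30.0, 900.0, 4000.0)
    mets_per_state: tuple[float, float, float] = (1.2, 2.0, 4.0)
    minute_noise: bool = False  # Poisson counts/steps and jittered METs when True

    # device-discrepancy injection for the stream mode
    om_step_bias: float = -56.0
    om_step_noise_sd: float = 0.0
    om_extra_mvpa_per_day: int = 23

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.days_per_subject < 1:
            raise ConfigError("n_subjects and days_per_subject must be >= 1")
        for name in ("sigma_b", "sigma_w", "sigma_m_between", "sigma_m_within", "om_step_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not 0 <= self.wake_start_hour < 24:
            raise ConfigError("wake_start_hour must be in [0, 24)")
        if self.wake_minutes <= 0 or self.wake_start_hour * 60 + self.wake_minutes > 1440:
            raise ConfigError("wake window must fit within a single calendar day")
        P = np.asarray(self.state_transition, dtype=float)
        if P.shape != (3, 3) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ConfigError("state_transition must be a 3x3 stochastic matrix (rows sum to 1)")
        if self.nonwear_bouts_per_day < 0 or self.nonwear_bout_minutes < 0:
            raise ConfigError("non-wear bout counts/lengths must be nonnegative")
        if self.om_extra_mvpa_per_day < 0:
            raise ConfigError("om_extra_mvpa_per_day must be nonnegative")
        total_nonwear = self.nonwear_bouts_per_day * self.nonwear_bout_minutes
        if total_nonwear > 0 and self.wake_minutes < total_nonwear + self.nonwear_bouts_per_day + 1:
            raise ConfigError("wake_minutes too small for the injected non-wear bouts")

    @property
    def reference_level(self) -> float:
        return self.mu_m if self.reference_m is None else self.reference_m

    def bout_offsets(self) -> tuple[int, ...]:
        """Start offsets (minutes after wake start) of the injected bouts.

        Fixed clock offsets — evenly spaced by default — so that detection
        round-trips are exact rather than distributional.
        """
        if self.nonwear_bout_offsets is not None:
            offs = tuple(int(o) for o in self.nonwear_bout_offsets)
            for o in offs:
                if o < 0 or o + self.nonwear_bout_minutes > self.wake_minutes:
                    raise ConfigError(f"bout at offset {o} leaves the wake window")
            return offs
        k, blen = self.nonwear_bouts_per_day, self.nonwear_bout_minutes
        if k == 0 or blen == 0:
            return ()
        gap = (self.wake_minutes - k * blen) // (k + 1)
        if gap < 1:
            raise ConfigError("wake_minutes too small for the injected non-wear bouts")
        return tuple(gap * (i + 1) + blen * i for i in range(k))


def _subject_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _subject_rngs(config: SimConfig) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(config.seed).spawn(config.n_subjects)]


def simulate_paired_differences(config: SimConfig) -> pd.DataFrame:
    """Draw daily paired differences directly from the difference model.

    Returns one row per subject-day with columns ``subject_id, day, m, d,
    om_value, ag_value`` where ``ag = m - d/2`` and ``om = m + d/2`` so that
    ``om - ag == d`` exactly.
    """
    ids = _subject_ids(config.n_subjects)
    rows = []
    ref = config.reference_level
    for sid, rng in zip(ids, _subject_rngs(config)):
        b = rng.normal(0.0, config.sigma_b)
        u = rng.normal(0.0, config.sigma_m_between)
        m = config.mu_m + u + rng.normal(0.0, config.sigma_m_within, config.days_per_subject)
        eps = rng.normal(0.0, config.sigma_w, config.days_per_subject)
        d = config.delta0 + config.delta1 * (m - ref) + b + eps
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "day": np.arange(1, config.days_per_subject + 1),
                    "m": m,
                    "d": d,
                    "om_value": m + d / 2.0,
                    "ag_value": m - d / 2.0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _simulate_states(rng: np.random.Generator, days: int, minutes: int, P: np.ndarray) -> np.ndarray:
    """Markov state paths, shape (days, minutes); all days start sedentary."""
    cum = np.cumsum(P, axis=1)
    states = np.zeros((days, minutes), dtype=np.int8)
    u = rng.random((days, minutes))
    for t in range(1, minutes):
        states[:, t] = (u[:, t, None] > cum[states[:, t - 1]]).sum(axis=1)
    return states


def simulate_minute_streams(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate full minute-level paired streams plus ground truth.

    Returns ``(ag_minutes, om_minutes, om_daily, truth)``.  The truth frame
    carries the daily summaries implied by the generated minutes —
    ``ag_steps, om_steps, ag_mvpa_min, om_mvpa_min, wear_min`` and the
    derived paired quantities ``m_steps, d_steps, m_mvpa, d_mvpa`` — so that
    pipeline output can be compared exactly.

    With ``minute_noise=False`` every per-state minute value equals its
    configured mean, making daily totals exact functions of the state path.
    MVPA thresholds assumed by the truth bookkeeping are METs >= 3.0 and
    vm_counts >= 2690 on worn minutes.
    """
    P = np.asarray(config.state_transition, dtype=float)
    offsets = config.bout_offsets()
    T = config.wake_minutes
    nonwear = np.zeros(T, dtype=bool)
    for o in offsets:
        nonwear[o : o + config.nonwear_bout_minutes] = True
    worn = ~nonwear
    wear_min = int(worn.sum())

    ids = _subject_ids(config.n_subjects)
    day0 = pd.Timestamp(config.start_date)
    base_minutes = (
        day0
        + pd.to_timedelta(np.repeat(np.arange(config.days_per_subject), T), unit="D")
        + pd.to_timedelta(config.wake_start_hour * 60 + np.tile(np.arange(T), config.days_per_subject), unit="m")
    )
    dates = day0 + pd.to_timedelta(np.arange(config.days_per_subject), unit="D")

    steps_mu = np.asarray(config.steps_per_state, dtype=float)
    counts_mu = np.asarray(config.counts_per_state, dtype=float)
    mets_mu = np.asarray(config.mets_per_state, dtype=float)

    ag_frames, om_frames, daily_rows, truth_rows = [], [], [], []
    for sid, rng in zip(ids, _subject_rngs(config)):
        states = _simulate_states(rng, config.days_per_subject, T, P)
        if config.minute_noise:
            steps = rng.poisson(steps_mu[states]).astype(float)
            counts = rng.poisson(counts_mu[states]).astype(float)
            mets = np.clip(mets_mu[states] + rng.normal(0.0, 0.15, states.shape), 0.1, None)
        else:
            steps = steps_mu[states].copy()
            counts = counts_mu[states].copy()
            mets = mets_mu[states].copy()

        # OM-only MVPA: raise METs of worn sub-moderate minutes to the
        # threshold, leaving counts below the AG cut-point.
        for day in range(config.days_per_subject):
            eligible = np.flatnonzero(worn & (mets[day] < 3.0) & (counts[day] < 2690))
            if len(eligible) < config.om_extra_mvpa_per_day:
                raise ConfigError(
                    f"day {day} has only {len(eligible)} eligible minutes for "
                    f"om_extra_mvpa_per_day={config.om_extra_mvpa_per_day}"
                )
            pick = rng.choice(eligible, size=config.om_extra_mvpa_per_day, replace=False)
            mets[day, pick] = 3.0

        # injected non-wear: AG reads zero; OM stays present at resting METs
        counts[:, nonwear] = 0.0
        steps[:, nonwear] = 0.0
        mets[:, nonwear] = 1.0

        ag_steps_day = steps.sum(axis=1).round().astype(np.int64)
        om_noise = rng.normal(0.0, config.om_step_noise_sd, config.days_per_subject) if config.om_step_noise_sd > 0 else 0.0
        om_steps_day = np.maximum(0, np.round(ag_steps_day + config.om_step_bias + om_noise)).astype(np.int64)
        ag_mvpa_day = ((counts >= 2690.0) & worn).sum(axis=1).astype(np.int64)
        om_mvpa_day = ((mets >= 3.0) & worn).sum(axis=1).astype(np.int64)

        ag_frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "timestamp": base_minutes,
                    "vm_counts": counts.round().astype(np.int64).ravel(),
                    "steps": steps.round().astype(np.int64).ravel(),
                }
            )
        )
        om_frames.append(
            pd.DataFrame({"subject_id": sid, "timestamp": base_minutes, "mets": mets.ravel()})
        )
        daily_rows.append(pd.DataFrame({"subject_id": sid, "date": dates, "steps": om_steps_day}))
        truth_rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "date": dates,
                    "ag_steps": ag_steps_day,
                    "om_steps": om_steps_day,
                    "ag_mvpa_min": ag_mvpa_day,
                    "om_mvpa_min": om_mvpa_day,
                    "wear_min": wear_min,
                }
            )
        )

    ag = pd.concat(ag_frames, ignore_index=True)
    om = pd.concat(om_frames, ignore_index=True)
    om_daily = pd.concat(daily_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    truth["m_steps"] = (truth["om_steps"] + truth["ag_steps"]) / 2.0
    truth["d_steps"] = (truth["om_steps"] - truth["ag_steps"]).astype(float)
    truth["m_mvpa"] = (truth["om_mvpa_min"] + truth["ag_mvpa_min"]) / 2.0
    truth["d_mvpa"] = (truth["om_mvpa_min"] - truth["ag_mvpa_min"]).astype(float)
    return ag, om, om_daily, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth[TRUTH_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime(epoch_io.DATE_FORMAT)
    out.to_csv(path, index=False, lineterminator="\r\n")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    df["date"] = pd.to_datetime(df["date"], format=epoch_io.DATE_FORMAT)
    return df


def make_reference_dataset(path, config: SimConfig = SimConfig()) -> dict[str, Path]:
    """Write the three pipeline input CSVs plus the truth CSV under ``path``.

    Returns the mapping of logical names to file paths: ``ag_minutes``,
    ``om_minutes``, ``om_daily``, ``truth``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ag, om, om_daily, truth = simulate_minute_streams(config)
    files = {
        "ag_minutes": path / "ag_minutes.csv",
        "om_minutes": path / "om_minutes.csv",
        "om_daily": path / "om_daily_steps.csv",
        "truth": path / "truth.csv",
    }
    epoch_io.write_ag_minutes(ag, files["ag_minutes"])
    epoch_io.write_om_minutes(om, files["om_minutes"])
    epoch_io.write_om_daily(om_daily, files["om_daily"])
    write_truth(truth, files["truth"])
    return files
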