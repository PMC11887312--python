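"""Multilevel agreement statistics for paired device outcomes.

The model throughout is the Gaussian random-intercept model

    y_ij = x_ij' beta + b_i + e_ij,    b_i ~ N(0, sigma2_b),  e_ij ~ N(0, sigma2_w)

for subject i and repeated daily observation j, estimated by REML.  The REML
criterion is profiled analytically over ``beta`` and the residual variance,
leaving a one-dimensional search over the variance ratio
``lambda = sigma2_b / sigma2_w``, which is minimised by a bracketed scalar
search.  Negative between-subject variance solutions are truncated at the
``lambda = 0`` boundary and flagged.

Three front ends are provided:

* :func:`fit_random_intercept` — intercept-only fit (overall mean and SE of
  a repeated outcome, plus the two variance components);
* :func:`bland_altman_multilevel` — intercept-only fit of the paired
  differences, with limits of agreement
  ``mu_d +/- multiplier * sqrt(sigma2_b + sigma2_w)`` (total variance of a
  new single difference; multiplier defaults to 1.96, no small-sample t
  correction);
* :func:`fit_proportional_bias` — difference regressed on the uncentred
  pairwise mean, with a Wald z test on the slope (no Satterthwaite degrees
  of freedom — a documented limitation).
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "IdentifiabilityError",
    "RankDeficiencyError",
    "VarianceComponents",
    "AgreementResult",
    "ProportionalBiasResult",
    "fit_random_intercept",
    "bland_altman_multilevel",
    "fit_proportional_bias",
    "make_pairs",
    "agreement_report",
]

_LAMBDA_MAX = 1e8
_DEGENERATE_RTOL = 1e-12


class IdentifiabilityError(ValueError):
    """The grouping structure cannot identify the model."""


class RankDeficiencyError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


@dataclass(frozen=True)
class VarianceComponents:
    """REML estimates from an intercept-only random-intercept fit."""

    mu: float
    se_mu: float
    sigma2_b: float
    sigma2_w: float
    n_subjects: int
    n_obs: int
    at_boundary: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class AgreementResult:
    """Mean difference, variance components and limits of agreement."""

    components: VarianceComponents
    loa_lower: float
    loa_upper: float
    loa_multiplier: float = 1.96

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(self.components.sigma2_b + self.components.sigma2_w))


@dataclass(frozen=True)
class ProportionalBiasResult:
    """Slope of difference on pairwise mean from the random-intercept model."""

    beta0: float
    beta1: float
    se_beta1: float
    p_beta1: float
    sigma2_b: float
    sigma2_w: float
    n_subjects: int = 0
    n_obs: int = 0
    at_boundary: bool = False
    degenerate: bool = False


def _as_arrays(values, subjects) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(values, Mapping):
        if subjects is not None:
            raise ValueError("pass either a mapping or (values, subjects), not both")
        y = np.concatenate([np.asarray(v, dtype=float) for v in values.values()])
        labels = np.concatenate([np.repeat(k, len(v)) for k, v in values.items()])
        return y, labels
    if subjects is None:
        raise ValueError("subjects required when values is not a mapping")
    return np.asarray(values, dtype=float), np.asarray(subjects)


def _reml_profile(y: np.ndarray, codes: np.ndarray, X: np.ndarray):
    """Profile-REML fit; returns (beta, cov_beta, sigma2_b, sigma2_w, at_boundary)."""
    n, p = X.shape
    n_groups = int(codes.max()) + 1
    n_i = np.bincount(codes, minlength=n_groups).astype(float)
    Sx = np.column_stack([np.bincount(codes, weights=X[:, k], minlength=n_groups) for k in range(p)])
    Sy = np.bincount(codes, weights=y, minlength=n_groups)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def solve(lam: float):
        a = lam / (1.0 + n_i * lam)
        XtVX = XtX - (Sx * a[:, None]).T @ Sx
        XtVy = Xty - Sx.T @ (a * Sy)
        beta = np.linalg.solve(XtVX, XtVy)
        q = yty - float(a @ (Sy**2)) - float(beta @ XtVy)
        return beta, XtVX, max(q, 0.0)

    def crit(lam: float) -> float:
        _, XtVX, q = solve(lam)
        sign, logdet = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return (
            (n - p) * np.log(max(q, 1e-300) / (n - p))
            + float(np.sum(np.log1p(n_i * lam)))
            + logdet
        )

    def score(lam: float) -> float:
        # d crit / d lambda via the REML score: tr(P ZZ') - (n-p)/Q * ||Z' P y||^2,
        # expressed through the group sums (P is the REML projection matrix).
        beta, XtVX, q = solve(lam)
        shrink = 1.0 + n_i * lam
        tr_vzz = float(np.sum(n_i / shrink))
        W = Sx / shrink[:, None]
        XtVX_inv = np.linalg.inv(XtVX)
        tr_fix = float(np.einsum("ij,jk,ik->", W, XtVX_inv, W))
        t = (Sy - Sx @ beta) / shrink
        return tr_vzz - tr_fix - (n - p) / max(q, 1e-300) * float(t @ t)

    grid = np.concatenate(([0.0], np.logspace(-10, np.log10(_LAMBDA_MAX), 73)))
    svals = np.array([score(l) for l in grid])
    # stationary points lie where the score crosses zero from below
    candidates = [0.0] if svals[0] >= 0 else []
    for k in range(len(grid) - 1):
        if svals[k] < 0 <= svals[k + 1]:
            candidates.append(float(optimize.brentq(score, grid[k], grid[k + 1], xtol=1e-14, rtol=1e-15)))
    if svals[-1] < 0:  # criterion still decreasing at the cap
        candidates.append(float(grid[-1]))
    if not candidates:
        candidates = [0.0]
    lam_hat = min(candidates, key=crit)
    if lam_hat < 1e-12:
        lam_hat = 0.0
    beta, XtVX, q = solve(lam_hat)
    sigma2_w = q / (n - p)
    sigma2_b = lam_hat * sigma2_w
    cov_beta = sigma2_w * np.linalg.inv(XtVX)
    return beta, cov_beta, sigma2_b, sigma2_w, lam_hat == 0.0


def _prepare_groups(y: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int]:
    if y.ndim != 1 or len(y) != len(labels):
        raise ValueError("values and subjects must be one-dimensional and equally long")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    _, codes = np.unique(labels, return_inverse=True)
    n_groups = int(codes.max()) + 1 if len(codes) else 0
    if n_groups < 2:
        raise IdentifiabilityError("at least two subjects are required to separate variance components")
    return codes, n_groups


def fit_random_intercept(
    values, subjects=None, *, force_zero_between: bool = False
) -> VarianceComponents:
    """REML fit of the intercept-only random-intercept model.

    Parameters
    ----------
    values
        Either a mapping ``{subject: sequence of observations}`` or a flat
        array of observations (then ``subjects`` gives the matching labels).
    force_zero_between
        Fix ``sigma2_b = 0`` (single-level model); also applied
        automatically, with a warning, when every subject contributes a
        single observation and the decomposition is unidentifiable.

    Notes
    -----
    ``se_mu`` is the plug-in GLS standard error at the REML solution, equal
    on balanced data to ``sqrt(MSB / (a * n))`` from the one-way ANOVA.  A
    zero-variance (all values identical) input returns the common value with
    zero variances and a degenerate-fit warning.
    """
    y, labels = _as_arrays(values, subjects)
    codes, n_groups = _prepare_groups(y, labels)
    n = len(y)
    n_i = np.bincount(codes)

    if np.ptp(y) == 0.0:
        warnings.warn("all observations identical; degenerate zero-variance fit", stacklevel=2)
        return VarianceComponents(float(y[0]), 0.0, 0.0, 0.0, n_groups, n, True, True)

    singleton_only = n_i.max() == 1
    if singleton_only and not force_zero_between:
        warnings.warn(
            "every subject has a single observation; between-subject variance is "
            "unidentifiable and is fixed at 0",
            stacklevel=2,
        )
    if force_zero_between or singleton_only:
        mu = float(np.mean(y))
        sigma2_w = float(np.sum((y - mu) ** 2) / (n - 1))
        return VarianceComponents(
            mu, float(np.sqrt(sigma2_w / n)), 0.0, sigma2_w, n_groups, n, True, False
        )

    X = np.ones((n, 1))
    beta, cov, s2b, s2w, boundary = _reml_profile(y, codes, X)
    return VarianceComponents(
        float(beta[0]), float(np.sqrt(cov[0, 0])), float(s2b), float(s2w), n_groups, n, boundary, False
    )


def make_pairs(daily: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Build the paired-difference table for one outcome.

    ``outcome`` is ``"steps"`` (uses ``om_steps``/``ag_steps``) or ``"mvpa"``
    (uses ``om_mvpa_min``/``ag_mvpa_min``).  Emits columns ``subject_id,
    date, om_value, ag_value, d, m`` with ``d = om - ag`` and
    ``m = (om + ag) / 2``.
    """
    cols = {"steps": ("om_steps", "ag_steps"), "mvpa": ("om_mvpa_min", "ag_mvpa_min")}
    try:
        om_col, ag_col = cols[outcome]
    except KeyError:
        raise ValueError(f"unknown outcome {outcome!r}; expected 'steps' or 'mvpa'") from None
    out = pd.DataFrame(
        {
            "subject_id": daily["subject_id"],
            "date": daily["date"],
            "om_value": daily[om_col].astype(float),
            "ag_value": daily[ag_col].astype(float),
        }
    )
    out["d"] = out["om_value"] - out["ag_value"]
    out["m"] = (out["om_value"] + out["ag_value"]) / 2.0
    return out.reset_index(drop=True)


def bland_altman_multilevel(
    pairs: pd.DataFrame, multiplier: float = 1.96, *, force_zero_between: bool = False
) -> AgreementResult:
    """Limits of agreement from the random-intercept fit of the differences.

    ``LoA = mu_d +/- multiplier * sqrt(sigma2_b + sigma2_w)`` — the total
    variance of a single new difference, yielding bounds symmetric about the
    mean difference.
    """
    comp = fit_random_intercept(
        pairs["d"].to_numpy(), pairs["subject_id"].to_numpy(), force_zero_between=force_zero_between
    )
    half = multiplier * np.sqrt(comp.sigma2_b + comp.sigma2_w)
    return AgreementResult(comp, float(comp.mu - half), float(comp.mu + half), float(multiplier))


def fit_proportional_bias(pairs: pd.DataFrame) -> ProportionalBiasResult:
    """REML fit of ``d_ij = beta0 + beta1 * m_ij + b_i + e_ij``.

    The pairwise mean enters uncentred.  The slope is tested with a Wald z
    statistic.  A noise-free (zero-residual) input returns the exactly
    interpolating coefficients with zero variances and a warning.
    """
    y = pairs["d"].to_numpy(dtype=float)
    m = pairs["m"].to_numpy(dtype=float)
    labels = pairs["subject_id"].to_numpy()
    codes, n_groups = _prepare_groups(y, labels)
    if np.ptp(m) == 0.0:
        raise RankDeficiencyError("pairwise mean m is constant; slope is not estimable")
    n = len(y)
    X = np.column_stack([np.ones(n), m])

    beta_ols, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta_ols) ** 2))
    scale = max(float(y @ y), float(np.sum((y - y.mean()) ** 2)), 1.0)
    if rss <= _DEGENERATE_RTOL * scale:
        warnings.warn("differences lie exactly on a line in m; degenerate zero-variance fit", stacklevel=2)
        return ProportionalBiasResult(
            float(beta_ols[0]), float(beta_ols[1]), 0.0, float("nan"), 0.0, 0.0, n_groups, n, True, True
        )

    beta, cov, s2b, s2w, boundary = _reml_profile(y, codes, X)
    se1 = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se1
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ProportionalBiasResult(
        float(beta[0]), float(beta[1]), se1, p, float(s2b), float(s2w), n_groups, n, boundary, False
    )


def agreement_report(result: AgreementResult, bias: ProportionalBiasResult) -> dict:
    """JSON-serialisable summary for one outcome."""
    c = result.components
    return {
        "mu": c.mu,
        "se": c.se_mu,
        "sigma2_b": c.sigma2_b,
        "sigma2_w": c.sigma2_w,
        "n_subjects": c.n_subjects,
        "n_obs": c.n_obs,
        "loa": [result.loa_lower, result.loa_upper],
        "loa_multiplier": result.loa_multiplier,
        "slope": {
            "est": bias.beta1,
            "se": bias.se_beta1,
            "p": None if np.isnan(bias.p_beta1) else bias.p_beta1,
            "intercept": bias.beta0,
        },
    }
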