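"""Independent reference implementations used to check the package.

These deliberately use different algorithmic routes from the package code:
interval enumeration instead of linear chaining for non-wear, closed-form
one-way ANOVA identities and dense-matrix likelihood maximisation instead of
the profiled group-sum REML, and plain set intersection instead of a
database-style join.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


# ---------------------------------------------------------------------------
# non-wear: brute-force enumeration of qualifying intervals


def _rle(counts):
    runs = []
    i = 0
    n = len(counts)
    while i < n:
        j = i
        while j < n and (counts[j] == 0) == (counts[i] == 0):
            j += 1
        runs.append((counts[i] == 0, i, j - i))
        i = j
    return runs


def nonwear_oracle(counts, window: int, tol: int, flank: int) -> np.ndarray:
    """Wear mask by enumerating every candidate interval independently.

    An interval qualifies when it starts and ends on zero minutes, spans at
    least ``window`` minutes, and every nonzero run strictly inside it has
    length <= ``tol`` with at least ``flank`` zeros immediately on each side
    (in the full stream).  A minute is non-worn iff it lies in some
    qualifying interval.
    """
    counts = np.asarray(counts)
    n = len(counts)
    nonworn = np.zeros(n, dtype=bool)
    runs = _rle(counts)
    zero_runs = [r for r in runs if r[0]]
    run_index = {r[1]: k for k, r in enumerate(runs)}
    for zi, (_, s, _) in enumerate(zero_runs):
        for _, es, el in zero_runs[zi:]:
            e = es + el
            if e - s < window:
                continue
            ok = True
            k = run_index[s]
            while runs[k][1] + runs[k][2] < e:
                is_zero, rs, rl = runs[k]
                if not is_zero:
                    left = runs[k - 1][2] if k > 0 and runs[k - 1][0] else 0
                    right = runs[k + 1][2] if k + 1 < len(runs) and runs[k + 1][0] else 0
                    if rl > tol or left < flank or right < flank:
                        ok = False
                        break
                k += 1
            if ok:
                nonworn[s:e] = True
    return ~nonworn


# ---------------------------------------------------------------------------
# REML: balanced one-way ANOVA closed form and dense-matrix maximisation


def balanced_anova_reml(y: np.ndarray):
    """Closed-form REML for a balanced one-way layout ``y`` of shape (a, n).

    Returns (mu, se_mu, sigma2_b, sigma2_w) with the between component
    truncated at zero (and the residual refit) at the boundary.
    """
    a, n = y.shape
    gm = y.mean()
    rowm = y.mean(axis=1)
    msb = n * np.sum((rowm - gm) ** 2) / (a - 1)
    mse = np.sum((y - rowm[:, None]) ** 2) / (a * (n - 1))
    s2b = (msb - mse) / n
    if s2b < 0:
        N = a * n
        s2w = np.sum((y - gm) ** 2) / (N - 1)
        return gm, np.sqrt(s2w / N), 0.0, s2w
    return gm, np.sqrt(msb / (a * n)), s2b, mse


def neg2_reml_loglik(y, groups, X, sigma2_b, sigma2_w):
    """-2 x REML log-likelihood (up to a constant) via dense matrices."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    _, codes = np.unique(groups, return_inverse=True)
    Z = np.eye(codes.max() + 1)[codes]
    V = sigma2_w * np.eye(len(y)) + sigma2_b * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return (
        float(np.linalg.slogdet(V)[1])
        + float(np.linalg.slogdet(XtViX)[1])
        + float(r @ Vi @ r)
    )


def gridsearch_reml(y, groups, X=None, refine: bool = True):
    """Maximise the REML log-likelihood by grid search plus Nelder-Mead.

    Returns (mu..., sigma2_b, sigma2_w); the search is over the positive
    orthant in log-variance space with the boundary sigma2_b = 0 included.
    """
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((len(y), 1))
    scale = max(np.var(y), 1e-6)
    grid = scale * np.logspace(-4, 2, 40)
    best = None
    for s2b in np.concatenate(([0.0], grid)):
        for s2w in grid:
            val = neg2_reml_loglik(y, groups, X, s2b, s2w)
            if best is None or val < best[0]:
                best = (val, s2b, s2w)
    _, s2b, s2w = best
    if refine:
        def obj(p):
            b, w = np.exp(p)
            return neg2_reml_loglik(y, groups, X, b, w)

        if s2b > 0:
            res = optimize.minimize(
                obj, np.log([s2b, s2w]), method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 5000},
            )
            cand = np.exp(res.x)
        else:
            res = optimize.minimize_scalar(
                lambda p: neg2_reml_loglik(y, groups, X, 0.0, np.exp(p)),
                bracket=(np.log(s2w) - 1, np.log(s2w) + 1),
                options={"xtol": 1e-13},
            )
            cand = np.array([0.0, np.exp(res.x)])
        # keep whichever is better, boundary included
        if neg2_reml_loglik(y, groups, X, *cand) <= best[0]:
            s2b, s2w = cand
    # GLS fixed effects at the optimum
    _, codes = np.unique(groups, return_inverse=True)
    Z = np.eye(codes.max() + 1)[codes]
    V = s2w * np.eye(len(y)) + s2b * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    cov = np.linalg.inv(XtViX)
    return beta, cov, float(s2b), float(s2w)
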