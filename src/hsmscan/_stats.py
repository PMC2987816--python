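"""Vectorised test statistics used by the permutation and sliding-window
machinery.

Scalar entry points elsewhere defer to scipy/statsmodels; these row-wise
implementations exist because a 334-window multi-scale scan evaluates
~W^2/2 placements, and a 10,000-shuffle permutation evaluates as many
statistics again — per-call scipy overhead dominates at that scale.  Both
are cross-checked against scipy / statsmodels and against brute-force
oracles in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["rowwise_kruskal", "rowwise_ols", "residualize"]


def rowwise_kruskal(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kruskal–Wallis H and chi-square p for each row of ``values``.

    ``values``: (m, n) array, each row one dataset over the same n samples.
    ``groups``: length-n integer labels.  Midranks with tie correction; df =
    (number of non-empty groups) - 1.  Rows where every value is identical
    get H = 0, p = 1 (documented convention).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("Kruskal–Wallis needs at least two groups")
    m, n = values.shape
    counts = np.bincount(inv, minlength=k).astype(float)

    ranks = stats.rankdata(values, axis=1)
    # per-group rank sums via one matmul
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inv] = 1.0
    rank_sums = ranks @ onehot  # (m, k)
    h = 12.0 / (n * (n + 1)) * ((rank_sums**2) / counts).sum(axis=1) - 3.0 * (n + 1)

    # tie correction per row: sum(t^3 - t) over tied groups
    sorted_vals = np.sort(values, axis=1)
    new_run = np.ones_like(sorted_vals, dtype=bool)
    new_run[:, 1:] = sorted_vals[:, 1:] != sorted_vals[:, :-1]
    # run lengths per row
    tie_term = np.empty(m)
    for i in range(m):  # loop over rows only when ties exist in that row
        starts = np.flatnonzero(new_run[i])
        t = np.diff(np.append(starts, n)).astype(float)
        tie_term[i] = (t**3 - t).sum()
    correction = 1.0 - tie_term / (n**3 - n)
    degenerate = correction <= 0  # all values identical
    h = np.where(degenerate, 0.0, h / np.where(degenerate, 1.0, correction))
    p = np.where(degenerate, 1.0, stats.chi2.sf(h, k - 1))
    return h, p


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of ``y`` (…, n) on ``[1, covariates]`` via least squares.

    ``covariates`` is (n,) or (n, c)."""
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError("covariate rows must match sample count")
    Z = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear covariate")
    beta, *_ = np.linalg.lstsq(Z, np.atleast_2d(y).T, rcond=None)
    res = np.atleast_2d(y) - (Z @ beta).T
    return res.reshape(y.shape)


def rowwise_ols(
    values: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, t and two-sided p of the ``x`` coefficient in an OLS of each
    row of ``values`` on ``[1, x, covariates]``.

    Uses the Frisch–Waugh partial-regression identity: residualise both the
    response rows and ``x`` on the nuisance design, then simple regression
    with df = n - 2 - (number of covariates).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    x = np.asarray(x, dtype=float)
    n = values.shape[1]
    n_cov = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        n_cov = cov.shape[1]
        x = residualize(x, cov)
        values = residualize(values, cov)
    xc = x - x.mean()
    yc = values - values.mean(axis=1, keepdims=True)
    ssx = float(xc @ xc)
    if ssx <= 0:
        raise ValueError("degenerate genotype: dosage has no variance")
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError(f"too few samples (n={n}) for the design")
    slope = yc @ xc / ssx
    sse = (yc**2).sum(axis=1) - slope**2 * ssx
    sse = np.maximum(sse, 0.0)
    se = np.sqrt(sse / df / ssx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.where(slope == 0, 0.0, np.inf * np.sign(slope)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return slope, t, p
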