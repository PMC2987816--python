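"""Stage 3: empirical-Bayes differential-methylation calling per ROI.

Case/control status y_s is modelled by logistic regression on the
methylation values of the individual 100-bp proxies inside a region of
interest (ROI).  With ~as many proxies as samples the per-proxy
coefficients are treated as draws from a common distribution with mean
zero and variance sigma^2, and the null of no differential methylation
becomes H0: sigma^2 = 0.  The score test for that null (the Goeman global
test) is the quadratic form

    Q = (y - ybar)' X X' (y - ybar) / nprox

with X the sample x proxy matrix after per-proxy centering.  Inference is
by permutation of the case/control labels (primary) with a moment-matched
scaled chi-square p as an asymptotic advisory.  FDR over many ROIs is
estimated two ways: Storey q-values (pi0 at lambda = 0.5) and a direct
permutation FDR from the same label shuffles applied to every ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MethylationMatrix, Region, SampleMetadata

__all__ = [
    "Roi",
    "RoiTestResult",
    "global_test_statistic",
    "roi_pvalue",
    "qvalues",
    "permutation_fdr",
    "dmr_scan",
    "dmr_table",
    "rois_from_regions",
    "permutation_moments",
]


@dataclass
class Roi:
    """A region of interest (typically 500–4000 bp) with its proxy windows."""

    region: Region
    proxy_grid_indices: np.ndarray  # 0-based grid indices of the 100-bp proxies

    @property
    def nprox(self) -> int:
        return len(self.proxy_grid_indices)


@dataclass
class RoiTestResult:
    roi: Roi
    Q: float
    p_perm: float
    p_asymptotic: float
    q_value: float = np.nan
    perm_fdr: float = np.nan


def _prepare(M: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Validate and center: returns (X sample x proxy centered, y)."""
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    if M.ndim != 2 or M.shape[0] == 0:
        raise ValueError("M must be nprox x n_samples with nprox >= 1")
    if y.shape != (M.shape[1],):
        raise ValueError("y length must match the sample axis of M")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if np.isnan(M).all(axis=1).any():
        raise ValueError("a proxy has no observed values")
    if np.isnan(M).any():
        warnings.warn("missing proxy values mean-imputed per proxy", stacklevel=3)
        means = np.nanmean(M, axis=1)
        M = np.where(np.isnan(M), means[:, None], M)
    X = (M - M.mean(axis=1, keepdims=True)).T  # samples x proxies, column-centered
    return X, y


def global_test_statistic(M: np.ndarray, y: np.ndarray, standardize: bool = False) -> float:
    """Score statistic Q for H0: sigma^2 = 0.

    ``M`` is proxy x sample methylation; ``y`` the 0/1 labels.  Q = 0 exactly
    when every proxy is uncorrelated with y in-sample.  ``standardize``
    additionally scales each proxy to unit variance before forming Q.
    """
    X, y = _prepare(M, y)
    if standardize:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    z = y - y.mean()
    v = X.T @ z
    return float(v @ v) / X.shape[1]


def permutation_moments(M: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact mean and variance of Q under uniform permutation of y.

    With B = X X' / nprox (double-centered because X's columns are centered,
    so all row sums of B vanish) and c the centered label vector, the
    moments follow from the permutation moments of the quadratic form
    z'Bz with z a random rearrangement of c.  Validated against exhaustive
    enumeration at small n in the test suite.
    """
    X, y = _prepare(M, y)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 for closed-form permutation moments")
    B = (X @ X.T) / X.shape[1]
    c = y - y.mean()
    S2 = float(c @ c)
    S4 = float((c**4).sum())
    T = float(np.trace(B))
    F = float((B**2).sum())  # = tr(B^2) for symmetric B
    D2 = float((np.diag(B) ** 2).sum())

    mu4 = S4 / n
    mu31 = -S4 / (n * (n - 1))
    mu22 = (S2**2 - S4) / (n * (n - 1))
    mu211 = (2 * S4 - S2**2) / (n * (n - 1) * (n - 2))
    mu1111 = (3 * S2**2 - 6 * S4) / (n * (n - 1) * (n - 2) * (n - 3))

    mean = T * S2 / (n - 1)
    e_q2 = (
        mu4 * D2
        - 4 * mu31 * D2
        + mu22 * (T**2 + 2 * F - 3 * D2)
        + mu211 * (-2 * T**2 - 4 * F + 12 * D2)
        + mu1111 * (T**2 + 2 * F - 6 * D2)
    )
    return mean, max(e_q2 - mean**2, 0.0)


def roi_pvalue(
    M: np.ndarray,
    y: np.ndarray,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
    perm_idx: np.ndarray | None = None,
) -> tuple[float, float]:
    """(permutation p, asymptotic p) for one ROI.

    The permutation p shuffles the case/control labels ((b+1)/(n_perm+1));
    the asymptotic p moment-matches Q to a scaled chi-square using the
    closed-form permutation mean and variance — advisory at these sample
    sizes.  ``perm_idx`` lets a caller share one shuffle stream across ROIs.
    """
    X, y = _prepare(M, y)
    nprox = X.shape[1]
    z = y - y.mean()
    q_obs = float(np.sum((X.T @ z) ** 2)) / nprox
    if perm_idx is None:
        if n_perm < 1000:
            warnings.warn(
                f"n_perm={n_perm} < 1000; reported results should use more shuffles",
                stacklevel=2,
            )
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perm_idx = np.argsort(rng.random((n_perm, len(y))), axis=1)
    Z = z[perm_idx]  # n_perm x n
    q_perm = ((Z @ X) ** 2).sum(axis=1) / nprox
    b = int((q_perm >= q_obs - 1e-12).sum())
    p_perm = (b + 1) / (perm_idx.shape[0] + 1)

    mean, var = permutation_moments(M, y)
    if var <= 0 or mean <= 0:
        p_asym = 1.0
    else:
        a = var / (2.0 * mean)
        nu = 2.0 * mean**2 / var
        p_asym = float(stats.chi2.sf(q_obs / a, nu))
    return p_perm, p_asym


def qvalues(p: np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single fixed lambda.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) m)); q_i = min over p_j >= p_i
    of pi0 * m * p_j / rank(p_j), which makes q monotone in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    pi0 = min(1.0, (p > lambda_).sum() / ((1.0 - lambda_) * m))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def permutation_fdr(p_observed: np.ndarray, p_null: np.ndarray) -> np.ndarray:
    """Permutation FDR at each observed p-value taken as the threshold.

    ``p_null`` is n_perm x m, from the same label shuffles applied jointly
    to all m ROIs.  FDR(t) = E_perm[#{null p <= t}] / max(1, #{obs p <= t}).
    """
    p_observed = np.asarray(p_observed, dtype=float)
    p_null = np.atleast_2d(np.asarray(p_null, dtype=float))
    if p_null.shape[1] != p_observed.size:
        raise ValueError("null matrix must have one column per observed ROI")
    out = np.empty(p_observed.size)
    for i, t in enumerate(p_observed):
        expected_false = (p_null <= t).sum(axis=1).mean()
        observed = max(1, int((p_observed <= t).sum()))
        out[i] = min(1.0, expected_false / observed)
    return out


def rois_from_regions(matrix: MethylationMatrix, regions: list[Region]) -> list[Roi]:
    """Build ROIs by collecting the unmasked proxies inside each region;
    regions with no proxies are skipped with a warning."""
    rois = []
    for region in regions:
        cols = matrix.grid.windows_in_region(region)
        if cols.size == 0:
            warnings.warn(f"ROI {region} has no proxies — skipped", stacklevel=2)
            continue
        rois.append(Roi(region, cols))
    return rois


def dmr_scan(
    matrix: MethylationMatrix,
    metadata: SampleMetadata,
    rois: list[Roi],
    n_perm: int = 2000,
    seed: int = 0,
) -> list[RoiTestResult]:
    """Run the global test over every ROI with one shared permutation stream,
    then attach Storey q-values and permutation FDR."""
    if not rois:
        raise ValueError("no ROIs to test")
    y = metadata.status_for(matrix.sample_ids)
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, len(y))), axis=1)

    results = []
    null_ps = np.empty((n_perm, len(rois)))
    for j, roi in enumerate(rois):
        M = matrix.scores[:, roi.proxy_grid_indices].T  # proxies x samples
        X, yv = _prepare(M, y)
        z = yv - yv.mean()
        q_obs = float(np.sum((X.T @ z) ** 2)) / roi.nprox
        Z = z[perm_idx]
        q_perm = ((Z @ X) ** 2).sum(axis=1) / roi.nprox
        b = int((q_perm >= q_obs - 1e-12).sum())
        p_perm = (b + 1) / (n_perm + 1)
        # null p for each permutation: rank of its Q among all permutations
        # (leave-self-in empirical p, same (b+1)/(n+1) convention)
        ranks = stats.rankdata(-q_perm, method="max")
        null_ps[:, j] = ranks / n_perm
        mean, var = permutation_moments(M, yv)
        if var <= 0 or mean <= 0:
            p_asym = 1.0
        else:
            a = var / (2.0 * mean)
            nu = 2.0 * mean**2 / var
            p_asym = float(stats.chi2.sf(q_obs / a, nu))
        results.append(RoiTestResult(roi, q_obs, p_perm, p_asym))

    p_obs = np.array([r.p_perm for r in results])
    qv = qvalues(p_obs)
    fdr = permutation_fdr(p_obs, null_ps)
    for r, q, f in zip(results, qv, fdr):
        r.q_value = float(q)
        r.perm_fdr = float(f)
    return results


def dmr_table(results: list[RoiTestResult]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.roi.region.chrom,
            "start": r.roi.region.start,
            "end": r.roi.region.end,
            "nprox": r.roi.nprox,
            "Q": r.Q,
            "p_perm": r.p_perm,
            "p_asymptotic": r.p_asymptotic,
            "q_value": r.q_value,
            "perm_fdr": r.perm_fdr,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
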