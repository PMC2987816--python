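"""Stage 1: regional methylation load versus genotype.

For each LD block around an association SNP, every sample's methylation
load is the mean of its 100-bp window scores across the block.  Samples are
grouped by tag-SNP genotype (rare-allele dosage 0/1/2) and compared with a
Kruskal–Wallis test, an additive-dosage linear regression (optionally with
age as a covariate), and an empirical permutation p obtained by shuffling
genotype assignment while holding the methylation loads fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import residualize, rowwise_kruskal
from .datamodel import GenotypeTable, MethylationMatrix, Region, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "BlockResult",
    "methylation_load",
    "kruskal_wallis",
    "genotype_regression",
    "permutation_pvalue",
    "block_scan",
    "results_table",
]


@dataclass
class BlockResult:
    """Per-block association summary (one row of a Table-1-style table)."""

    region: Region
    snp_id: str
    alleles: tuple[str, str]  # (common, rare)
    group_means: tuple[float, float, float]  # dosage 0 / 1 / 2
    n_per_group: tuple[int, int, int]
    kw_stat: float
    kw_p: float
    lr_slope: float
    lr_p: float
    age_p: float
    perm_p: float
    n_perm: int
    lr_p_bonferroni: float = np.nan


def methylation_load(matrix: MethylationMatrix, region: Region) -> np.ndarray:
    """Per-sample mean methylation over the unmasked windows fully inside
    ``region`` (NaN scores skipped pairwise).  Samples with more than half of
    the region's windows missing are flagged with a warning and still
    reported from the windows they do have."""
    cols = matrix.grid.windows_in_region(region)
    if cols.size == 0:
        raise ValueError(f"region {region} contains no unmasked windows")
    sub = matrix.scores[:, cols]
    n_missing = np.isnan(sub).sum(axis=1)
    flagged = np.flatnonzero(n_missing > 0.5 * cols.size)
    for i in flagged:
        warnings.warn(
            f"sample {matrix.sample_ids[i]}: >50% missing windows in {region}",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        return np.nanmean(sub, axis=1)


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected midranks) and chi-square p across
    genotype groups.  Pairs with missing value or group are dropped; all
    values identical returns (0, 1) by convention."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=float)
    keep = np.isfinite(values) & np.isfinite(groups)
    values, groups = values[keep], groups[keep]
    present = np.unique(groups)
    if len(present) < 2:
        raise ValueError("Kruskal–Wallis needs at least two non-empty groups")
    samples = [values[groups == g] for g in present]
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def genotype_regression(
    values: np.ndarray, dosages: np.ndarray, age: np.ndarray | None = None
) -> tuple[float, float, float]:
    """OLS of methylation load on additive rare-allele dosage (plus age when
    given): returns (slope, dosage p, age p — NaN without the covariate)."""
    values = np.asarray(values, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    keep = np.isfinite(values) & np.isfinite(dosages)
    if age is not None:
        age = np.asarray(age, dtype=float)
        keep &= np.isfinite(age)
    values, dosages = values[keep], dosages[keep]
    n = values.size
    if n < (5 if age is not None else 4):
        raise ValueError(f"too few complete samples (n={n}) for regression")
    if np.var(dosages) == 0:
        raise ValueError("degenerate genotype: dosage has no variance")
    X = [dosages]
    if age is not None:
        age = age[keep]
        X.append(age)
    X = sm.add_constant(np.column_stack(X))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariate")
    fit = sm.OLS(values, X).fit()
    slope = float(fit.params[1])
    lr_p = float(fit.pvalues[1])
    age_p = float(fit.pvalues[2]) if age is not None else float("nan")
    return slope, lr_p, age_p


def permutation_pvalue(
    values: np.ndarray,
    dosages: np.ndarray,
    stat: str = "lr",
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    age: np.ndarray | None = None,
) -> float:
    """Empirical p from shuffling genotype assignment over the fixed loads.

    ``stat="kw"`` counts permutations with H >= observed H; ``stat="lr"``
    counts |t| >= observed |t| for the dosage coefficient.  Reported as
    (b + 1) / (n_perm + 1), so the attainable floor is 1/(n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse empirical p", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    keep = np.isfinite(values) & np.isfinite(dosages)
    if age is not None:
        age = np.asarray(age, dtype=float)
        keep &= np.isfinite(age)
        age = age[keep]
    values, dosages = values[keep], dosages[keep]
    n = values.size

    # one genotype shuffle per permutation, as an index matrix
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)

    if stat == "kw":
        h_obs, _ = kruskal_wallis(values, dosages)
        if not np.isfinite(h_obs):
            raise ValueError("observed statistic not finite")
        # shuffling genotype labels over fixed values == shuffling values
        # over fixed labels; one vectorised call over all permutations
        h_perm, _ = rowwise_kruskal(values[perm_idx], dosages)
        b = int((h_perm >= h_obs - 1e-12).sum())
    elif stat == "lr":
        n_cov = 0
        if age is not None:
            # genotype is shuffled across samples; age stays attached, so
            # residualise the response and each shuffled dosage vector on age
            n_cov = 1
            y = residualize(values, age)
            x_obs = residualize(dosages, age)
            x_perm = residualize(dosages[perm_idx], age)
        else:
            y = values
            x_obs = dosages
            x_perm = dosages[perm_idx]
        df = n - 2 - n_cov

        def _t(xrows: np.ndarray) -> np.ndarray:
            xc = xrows - xrows.mean(axis=1, keepdims=True)
            yc = y - y.mean()
            num = xc @ yc
            den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(den > 0, num / den, 0.0)
            r = np.clip(r, -1.0, 1.0)
            with np.errstate(divide="ignore"):
                return r * np.sqrt(df) / np.sqrt(1.0 - r**2)

        t_obs = float(_t(x_obs[None, :])[0])
        if not np.isfinite(t_obs):
            raise ValueError("observed statistic not finite")
        t_perm = _t(x_perm)
        b = int((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum())
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return (b + 1) / (n_perm + 1)


def _group_stats(values: np.ndarray, dosages: np.ndarray):
    means, counts = [], []
    for d in (0.0, 1.0, 2.0):
        sel = dosages == d
        counts.append(int(sel.sum()))
        means.append(float(np.mean(values[sel])) if sel.any() else float("nan"))
    return tuple(means), tuple(counts)


def block_scan(
    matrix: MethylationMatrix,
    genotypes: GenotypeTable,
    regions: list[Region],
    snp_map: dict[str, str],
    metadata: SampleMetadata | None = None,
    n_perm: int = 10_000,
    perm_stat: str = "lr",
    seed: int = 0,
) -> list[BlockResult]:
    """One :class:`BlockResult` per region; ``snp_map`` maps region label to
    its tag SNP.  Grouping ignores case/control status by design.  Reports
    uncorrected p plus a Bonferroni column over the number of tested regions.
    """
    rng = np.random.default_rng(seed)
    age = metadata.age_for(matrix.sample_ids) if metadata is not None else None
    results: list[BlockResult] = []
    for region in regions:
        snp = snp_map.get(region.label) or snp_map.get(str(region))
        if snp is None or snp not in genotypes.snp_ids:
            logger.warning("region %s: no tag SNP genotyped — skipped", region)
            continue
        loads = methylation_load(matrix, region)
        dosages = genotypes.dosages_for(snp, matrix.sample_ids)
        keep = np.isfinite(loads) & np.isfinite(dosages)
        lv, dv = loads[keep], dosages[keep]
        av = age[keep] if age is not None else None
        means, counts = _group_stats(lv, dv)
        kw_h, kw_p = kruskal_wallis(lv, dv)
        slope, lr_p, age_p = genotype_regression(lv, dv, av)
        perm_p = permutation_pvalue(lv, dv, perm_stat, n_perm, rng, age=av)
        results.append(
            BlockResult(
                region=region,
                snp_id=snp,
                alleles=genotypes.alleles[snp],
                group_means=means,
                n_per_group=counts,
                kw_stat=kw_h,
                kw_p=kw_p,
                lr_slope=slope,
                lr_p=lr_p,
                age_p=age_p,
                perm_p=perm_p,
                n_perm=n_perm,
            )
        )
    m = len(results)
    for r in results:
        r.lr_p_bonferroni = min(1.0, r.lr_p * m)
    return results


def results_table(results: list[BlockResult]) -> pd.DataFrame:
    """Table-1-shaped frame: one row per block, genotype-group means and the
    three p-values."""
    rows = []
    for r in results:
        rows.append(
            {
                "chrom": r.region.chrom,
                "start": r.region.start,
                "end": r.region.end,
                "snp": r.snp_id,
                "common_allele": r.alleles[0],
                "rare_allele": r.alleles[1],
                "mean_00": r.group_means[0],
                "mean_01": r.group_means[1],
                "mean_02": r.group_means[2],
                "n_00": r.n_per_group[0],
                "n_01": r.n_per_group[1],
                "n_02": r.n_per_group[2],
                "kw_stat": r.kw_stat,
                "kw_p": r.kw_p,
                "lr_slope": r.lr_slope,
                "lr_p": r.lr_p,
                "age_p": r.age_p,
                "perm_p": r.perm_p,
                "n_perm": r.n_perm,
                "lr_p_bonferroni": r.lr_p_bonferroni,
            }
        )
    return pd.DataFrame(rows)
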