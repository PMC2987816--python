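"""Stage 2: multi-scale sliding-window scan across an LD block.

Every window size w from 1 up to the block's unmasked window count is slid
one window at a time over the *unmasked* window indices; each placement's
per-sample load is the mean of its w window scores (computed incrementally
via cumulative sums), and the placement is tested against tag-SNP dosage by
linear regression and (optionally) Kruskal–Wallis, exactly as at block
scale.  Placements are plotted/reported at the midpoint of their genomic
span; because placements slide over unmasked indices, a placement's genomic
span can include masked gaps — the output carries both the index range and
the genomic coordinates so gaps are visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import residualize, rowwise_kruskal, rowwise_ols
from .datamodel import MethylationMatrix, Region

__all__ = ["ScanProfile", "PeakCall", "scan_block", "peak_localise", "slope_profile", "scan_permutation"]


@dataclass
class ScanProfile:
    """All placements of one window size w across a block.

    Arrays are indexed by placement; ``start_index`` is the 1-based unmasked
    index of the placement's first window.
    """

    region: Region
    w: int
    start_index: np.ndarray
    genomic_start: np.ndarray
    genomic_end: np.ndarray
    midpoint: np.ndarray
    lr_p: np.ndarray
    lr_slope: np.ndarray
    kw_p: np.ndarray | None = None
    group_means: np.ndarray | None = None  # (n_placements, 3) dosage 0/1/2

    @property
    def n_placements(self) -> int:
        return len(self.start_index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "w": self.w,
                "start_index": self.start_index,
                "genomic_start": self.genomic_start,
                "genomic_end": self.genomic_end,
                "midpoint": self.midpoint,
                "lr_slope": self.lr_slope,
                "lr_p": self.lr_p,
            }
        )
        if self.kw_p is not None:
            df["kw_p"] = self.kw_p
        if self.group_means is not None:
            df[["mean_00", "mean_01", "mean_02"]] = self.group_means
        return df


@dataclass
class PeakCall:
    """Global best placement over all (w, placement) pairs, by LR p.

    Ties break toward smaller w, then the leftmost placement.  ``per_w``
    records each window size's own minimum so nesting of a narrow peak
    inside a broader one can be examined.
    """

    best_w: int
    best_start_index: int
    best_interval: Region
    best_lr_p: float
    best_kw_p: float
    per_w: pd.DataFrame = field(repr=False)


def _placement_loads(scores_unmasked: np.ndarray, w: int) -> np.ndarray:
    """(n_placements, n_samples) mean loads for window size w, via running
    sums over the unmasked-window axis."""
    csum = np.cumsum(scores_unmasked, axis=1)
    csum = np.concatenate([np.zeros((scores_unmasked.shape[0], 1)), csum], axis=1)
    loads = (csum[:, w:] - csum[:, :-w]) / w
    return loads.T


def _placement_coords(matrix: MethylationMatrix, region: Region, cols: np.ndarray, w: int):
    grid = matrix.grid
    starts_bp = grid.start + cols * grid.window_size_bp
    ends_bp = starts_bp + grid.window_size_bp - 1
    gstart = starts_bp[: len(cols) - w + 1]
    gend = ends_bp[w - 1 :]
    return gstart, gend, (gstart + gend) / 2.0


def scan_block(
    matrix: MethylationMatrix,
    dosages: np.ndarray,
    region: Region,
    sizes: str | list[int] = "all",
    tests: set[str] = frozenset({"kw", "lr"}),
    covariate: np.ndarray | None = None,
    group_means: bool = False,
) -> list[ScanProfile]:
    """Scan ``region`` at every requested window size, one profile per size."""
    grid = matrix.grid
    cols = grid.windows_in_region(region)
    W = cols.size
    if W == 0:
        raise ValueError(f"region {region} has no unmasked windows")
    dosages = np.asarray(dosages, dtype=float)
    if np.var(dosages[np.isfinite(dosages)]) == 0:
        raise ValueError("degenerate genotype: dosage has no variance")
    if sizes == "all":
        w_list = list(range(1, W + 1))
    else:
        w_list = sorted(int(w) for w in sizes)
        if any(w > W for w in w_list):
            warnings.warn(f"window sizes beyond {W} unmasked windows trimmed", stacklevel=2)
            w_list = [w for w in w_list if w <= W]
        if any(w < 1 for w in w_list):
            raise ValueError("window sizes must be >= 1")

    sub = matrix.scores[:, cols]  # samples x unmasked windows, genomic order
    profiles = []
    for w in w_list:
        loads = _placement_loads(sub, w)  # placements x samples
        slope, _, lr_p = rowwise_ols(loads, dosages, covariate)
        gstart, gend, mid = _placement_coords(matrix, region, cols, w)
        prof = ScanProfile(
            region=region,
            w=w,
            start_index=np.arange(1, W - w + 2),
            genomic_start=gstart,
            genomic_end=gend,
            midpoint=mid,
            lr_p=lr_p,
            lr_slope=slope,
        )
        if "kw" in tests:
            _, prof.kw_p = rowwise_kruskal(loads, dosages)
        if group_means:
            gm = np.full((loads.shape[0], 3), np.nan)
            for g in range(3):
                sel = dosages == g
                if sel.any():
                    gm[:, g] = loads[:, sel].mean(axis=1)
            prof.group_means = gm
        profiles.append(prof)
    return profiles


def peak_localise(profiles: list[ScanProfile]) -> PeakCall:
    """Global minimum LR p over all (w, placement); ties go to the smaller
    w, then the leftmost placement."""
    if not profiles:
        raise ValueError("no profiles given")
    best = None
    per_w_rows = []
    for prof in sorted(profiles, key=lambda p: p.w):
        if not np.isfinite(prof.lr_p).any():
            continue
        j = int(np.nanargmin(prof.lr_p))
        pmin = float(prof.lr_p[j])
        per_w_rows.append(
            {
                "w": prof.w,
                "start_index": int(prof.start_index[j]),
                "genomic_start": int(prof.genomic_start[j]),
                "genomic_end": int(prof.genomic_end[j]),
                "min_lr_p": pmin,
            }
        )
        if best is None or pmin < best[0]:
            best = (pmin, prof, j)
    if best is None:
        raise ValueError("all scan p-values are missing")
    pmin, prof, j = best
    interval = Region(
        prof.region.chrom,
        int(prof.genomic_start[j]),
        int(prof.genomic_end[j]),
        label=f"w{prof.w}",
    )
    kw = float(prof.kw_p[j]) if prof.kw_p is not None else float("nan")
    return PeakCall(
        best_w=prof.w,
        best_start_index=int(prof.start_index[j]),
        best_interval=interval,
        best_lr_p=pmin,
        best_kw_p=kw,
        per_w=pd.DataFrame(per_w_rows),
    )


def slope_profile(
    matrix: MethylationMatrix,
    dosages: np.ndarray,
    region: Region,
    w: int,
    covariate: np.ndarray | None = None,
) -> ScanProfile:
    """Regression-slope track for one window size (slope sign is per copy of
    the rare allele under the 0/1/2 dosage coding)."""
    (prof,) = scan_block(matrix, dosages, region, sizes=[w], tests={"lr"}, covariate=covariate)
    return prof


def scan_permutation(
    matrix: MethylationMatrix,
    dosages: np.ndarray,
    region: Region,
    w_list: list[int],
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "pointwise",
    covariate: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Permutation p-values for the LR |t| statistic at every placement.

    Genotype labels are shuffled once per permutation and applied to every
    placement and window size, preserving the spatial correlation of the
    methylation tracks.  ``pointwise`` returns per-placement empirical p;
    ``max_statistic`` returns family-wise-adjusted p by comparing each
    observed |t| with the permutation distribution of the maximum |t| over
    the whole (w, placement) family — an extension beyond the pointwise
    analysis.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("pointwise", "max_statistic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    grid = matrix.grid
    cols = grid.windows_in_region(region)
    dosages = np.asarray(dosages, dtype=float)
    n = dosages.size
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    x_perm = dosages[perm_idx]
    if covariate is not None:
        x_perm = residualize(x_perm, covariate)
        x_obs = residualize(dosages, covariate)
        n_cov = 1
    else:
        x_obs = dosages
        n_cov = 0
    df = n - 2 - n_cov

    sub = matrix.scores[:, cols]
    t_obs: dict[int, np.ndarray] = {}
    exceed: dict[int, np.ndarray] = {}
    max_t = np.zeros(n_perm)
    xp_c = x_perm - x_perm.mean(axis=1, keepdims=True)
    xp_ss = (xp_c**2).sum(axis=1)
    for w in w_list:
        loads = _placement_loads(sub, w)  # placements x samples
        if covariate is not None:
            loads = residualize(loads, covariate)
        yc = loads - loads.mean(axis=1, keepdims=True)
        yss = (yc**2).sum(axis=1)
        xo_c = x_obs - x_obs.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            r_obs = (yc @ xo_c) / np.sqrt(yss * (xo_c @ xo_c))
        r_obs = np.clip(np.nan_to_num(r_obs), -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t_obs[w] = np.abs(r_obs) * np.sqrt(df) / np.sqrt(1.0 - r_obs**2)
        num = yc @ xp_c.T  # placements x n_perm
        den = np.sqrt(np.outer(yss, xp_ss))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t_p = np.abs(r) * np.sqrt(df) / np.sqrt(1.0 - r**2)
        if mode == "pointwise":
            exceed[w] = (t_p >= t_obs[w][:, None] - 1e-12).sum(axis=1)
        else:
            max_t = np.maximum(max_t, t_p.max(axis=0))
    out: dict[int, np.ndarray] = {}
    for w in w_list:
        if mode == "pointwise":
            out[w] = (exceed[w] + 1) / (n_perm + 1)
        else:
            b = (max_t[None, :] >= t_obs[w][:, None] - 1e-12).sum(axis=1)
            out[w] = (b + 1) / (n_perm + 1)
    return out
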