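"""Core domain types shared by every analysis stage.

Coordinates are 1-based inclusive throughout (the convention of the hg18
coordinates this analysis was designed around); BED/BEDGRAPH ingestion in
:mod:`hsmscan.io` converts from 0-based half-open on the way in.

Methylation is carried as absolute scores in [0, 1] on a fixed grid of
100-bp windows (the output unit of Bayesian MeDIP deconvolution such as
BATMAN): 0 = unmethylated, 1 = fully methylated.  Windows falling in repeat
regions are excluded via a boolean mask; all user-facing window indices
count only unmasked windows, with genomic coordinates reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "GenomicWindowGrid",
    "MethylationMatrix",
    "GenotypeTable",
    "SampleMetadata",
    "SnpContext",
]


@dataclass(frozen=True)
class Region:
    """A genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region {self.label or self.chrom}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GenomicWindowGrid:
    """A fixed grid of equal-width windows with a repeat-exclusion mask.

    Window ``k`` (1-based, counting *all* grid windows) spans
    ``[start + (k-1)*window_size_bp, start + k*window_size_bp - 1]``.
    ``mask[k-1] == True`` marks window ``k`` as excluded (e.g. repeat
    region); analysis indices enumerate unmasked windows only.
    """

    chrom: str
    start: int
    n_windows: int
    window_size_bp: int = 100
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("grid needs at least one window")
        if self.window_size_bp < 1:
            raise ValueError("window_size_bp must be positive")
        if self.mask is None:
            self.mask = np.zeros(self.n_windows, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_windows,):
                raise ValueError("mask length must equal n_windows")

    # -- unmasked-index bookkeeping ---------------------------------------
    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    @property
    def unmasked_grid_indices(self) -> np.ndarray:
        """1-based grid indices of the unmasked windows, in genomic order."""
        return np.flatnonzero(~self.mask) + 1

    def grid_window_span(self, grid_index: int) -> Region:
        """Genomic span of grid window ``grid_index`` (1-based, masked or not)."""
        if not 1 <= grid_index <= self.n_windows:
            raise IndexError(f"grid window {grid_index} outside 1..{self.n_windows}")
        s = self.start + (grid_index - 1) * self.window_size_bp
        return Region(self.chrom, s, s + self.window_size_bp - 1)

    def window_to_coords(self, unmasked_index: int) -> Region:
        """Genomic span of the ``unmasked_index``-th unmasked window."""
        n = self.n_unmasked
        if not 1 <= unmasked_index <= n:
            raise IndexError(f"unmasked window {unmasked_index} outside 1..{n}")
        return self.grid_window_span(int(self.unmasked_grid_indices[unmasked_index - 1]))

    def coords_to_window(self, chrom: str, pos: int) -> int:
        """Unmasked index of the window containing ``pos`` (inverse of
        :meth:`window_to_coords` for any position inside an unmasked window)."""
        if chrom != self.chrom:
            raise ValueError(f"chromosome {chrom!r} not on this grid ({self.chrom!r})")
        offset = pos - self.start
        grid_index = offset // self.window_size_bp + 1
        if offset < 0 or grid_index > self.n_windows:
            raise IndexError(f"position {pos} outside the grid")
        if self.mask[grid_index - 1]:
            raise IndexError(f"position {pos} falls in a masked window")
        return int((~self.mask[:grid_index]).sum())

    def windows_in_region(self, region: Region, unmasked_only: bool = True) -> np.ndarray:
        """0-based *grid* indices of windows fully inside ``region``."""
        if region.chrom != self.chrom:
            return np.array([], dtype=int)
        starts = self.start + np.arange(self.n_windows) * self.window_size_bp
        ends = starts + self.window_size_bp - 1
        inside = (starts >= region.start) & (ends <= region.end)
        if unmasked_only:
            inside &= ~self.mask
        return np.flatnonzero(inside)


@dataclass
class MethylationMatrix:
    """Per-sample methylation scores on a shared window grid.

    ``scores`` is sample x window over *all* grid windows (masked columns are
    carried but ignored by analyses); missing values are NaN.
    """

    grid: GenomicWindowGrid
    sample_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        expected = (len(self.sample_ids), self.grid.n_windows)
        if self.scores.shape != expected:
            raise ValueError(f"scores shape {self.scores.shape} != {expected}")
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("methylation scores must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def unmasked_scores(self) -> np.ndarray:
        """Sample x unmasked-window view, columns in genomic order."""
        return self.scores[:, ~self.grid.mask]


@dataclass
class GenotypeTable:
    """Allele-dosage genotypes: samples x SNPs, dosage = count of the rare
    allele (0 = common homozygote, 1 = het, 2 = rare homozygote, NaN missing).

    The risk allele need not be the rare allele, so the common/rare allele
    labels are carried per SNP and reported with every result.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    alleles: dict[str, tuple[str, str]]  # snp_id -> (common, rare)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage shape mismatch")
        vals = self.dosage[np.isfinite(self.dosage)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage codes must be 0, 1, 2 or missing")
        for snp, (a, b) in self.alleles.items():
            if len(a) != 1 or len(b) != 1:
                raise ValueError(f"{snp}: allele labels must be single bases")

    def dosages_for(self, snp_id: str, sample_ids: list[str] | None = None) -> np.ndarray:
        j = self.snp_ids.index(snp_id)
        col = self.dosage[:, j]
        if sample_ids is None:
            return col
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return col[idx]


@dataclass
class SampleMetadata:
    """Case/control status (1/0), age in years, sex code, per sample."""

    sample_ids: list[str]
    status: np.ndarray
    age: np.ndarray
    sex: list[str] | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        n = len(self.sample_ids)
        if self.status.shape != (n,) or self.age.shape != (n,):
            raise ValueError("metadata arrays must match sample count")
        ok = np.isfinite(self.status)
        if not np.isin(self.status[ok], (0.0, 1.0)).all():
            raise ValueError("status must be 0 (control) or 1 (case)")
        if np.any(self.age[np.isfinite(self.age)] <= 0):
            raise ValueError("age must be positive when present")

    def age_for(self, sample_ids: list[str]) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return self.age[idx]

    def status_for(self, sample_ids: list[str]) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return self.status[idx]


_DNA = set("ACGTN")


@dataclass(frozen=True)
class SnpContext:
    """A SNP with flanking sequence — the substrate for CpG-SNP calls.

    ``left_flank``/``right_flank`` are the uppercase bases immediately 5' and
    3' of the polymorphic base on the given strand.  ``ancestral`` is a single
    base or ``None`` when the ancestral state is unknown.
    """

    snp_id: str
    position: int
    left_flank: str
    allele_a: str
    allele_b: str
    right_flank: str
    ancestral: str | None = None
    chrom: str = ""
    frequencies: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        for name, seq in (("left_flank", self.left_flank), ("right_flank", self.right_flank)):
            if not seq or not set(seq.upper()) <= _DNA:
                raise ValueError(f"{self.snp_id}: {name} must be non-empty ACGTN")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset({self.allele_a.upper(), self.allele_b.upper()})
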