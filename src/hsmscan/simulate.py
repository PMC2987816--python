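"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design this pipeline was built for: 60
female samples (30 case / 30 control), a tag SNP with rare/risk-allele
frequency 0.425 under Hardy–Weinberg, an LD block of 334 usable 100-bp
windows (masked repeat windows interleaved so the genomic span matches a
~46 kb block), per-window Gaussian noise with SD 0.14 clipped to [0, 1],
and a haplotype-driven methylation elevation: +0.048 per risk allele
inside a 9-window peak (unmasked windows 161–169) over a +0.016/allele
block-level background, on a baseline mean of 0.50.  Ages are
Normal(37, 6.6) and independent of genotype; case/control labels are
independent of methylation.  Optional knobs (age effect, case/control DMR
shift, AR(1) noise correlation) exist for covariate and calibration
testing and default to off.

Everything is reproducible from the config seed, and a truth record
accompanies each cohort for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import (
    GenomicWindowGrid,
    GenotypeTable,
    MethylationMatrix,
    Region,
    SampleMetadata,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "PyroSite",
    "simulate_cohort",
    "simulate_null",
    "simulate_pyro_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 60
    n_cases: int = 30
    maf: float = 0.425  # rare/risk-allele frequency of the tag SNP
    n_windows: int = 334  # usable (unmasked) 100-bp windows in the block
    window_size_bp: int = 100
    hsm_window_range: tuple[int, int] = (161, 169)  # unmasked indices, inclusive
    effect_block: float = 0.016  # per-allele shift outside the peak
    effect_peak: float = 0.048  # per-allele shift inside the peak
    baseline_mean: float = 0.50
    noise_sd: float = 0.14
    age_mean: float = 37.0
    age_sd: float = 6.6
    mask_fraction: float = 0.272  # interleaved repeat-masked windows
    seed: int = 0
    chrom: str = "chr16"
    grid_start: int = 52_357_008
    snp_id: str = "rs8050136"
    alleles: tuple[str, str] = ("C", "A")  # (common, rare/risk)
    age_effect: float = 0.0  # methylation shift per year, off by default
    dmr_effect: float = 0.0  # case-vs-control shift in dmr_window_ranges
    dmr_window_ranges: tuple[tuple[int, int], ...] = ()
    ar1_rho: float = 0.0  # optional along-block noise autocorrelation

    def __post_init__(self) -> None:
        if not 0 < self.maf < 1:
            raise ValueError("maf must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_cases > self.n_samples:
            raise ValueError("n_cases cannot exceed n_samples")
        lo, hi = self.hsm_window_range
        if not (1 <= lo <= hi <= self.n_windows):
            raise ValueError("hsm_window_range must lie within [1, n_windows]")
        if not 0 <= self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in [0, 1)")
        top = self.baseline_mean + 2 * max(self.effect_block, self.effect_peak, 0)
        bottom = self.baseline_mean + 2 * min(self.effect_block, self.effect_peak, 0)
        if top > 1 + 3 * self.noise_sd or bottom < -3 * self.noise_sd:
            warnings.warn("expected means pushed far outside (0, 1); clipping will bite")

    @property
    def hardy_weinberg(self) -> tuple[float, float, float]:
        q = self.maf
        return ((1 - q) ** 2, 2 * q * (1 - q), q**2)


@dataclass
class SimulationTruth:
    dosages: np.ndarray  # per-sample rare-allele count at the tag SNP
    effect_interval: tuple[int, int]  # unmasked indices carrying the peak
    effect_region: Region  # genomic span of the peak
    expected_means: np.ndarray  # 3 x n_windows (dosage 0/1/2, unmasked order)


def _per_window_effect(config: SimulationConfig) -> np.ndarray:
    eff = np.full(config.n_windows, config.effect_block)
    lo, hi = config.hsm_window_range
    eff[lo - 1 : hi] = config.effect_peak
    return eff


def _build_grid(config: SimulationConfig, rng: np.random.Generator) -> GenomicWindowGrid:
    n_total = int(round(config.n_windows / (1 - config.mask_fraction)))
    n_masked = n_total - config.n_windows
    mask = np.zeros(n_total, dtype=bool)
    if n_masked > 0:
        mask[rng.choice(n_total, size=n_masked, replace=False)] = True
    return GenomicWindowGrid(
        config.chrom, config.grid_start, n_total, config.window_size_bp, mask
    )


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[MethylationMatrix, GenotypeTable, SampleMetadata, SimulationTruth]:
    """Draw one cohort: per-window score = clip(baseline + dosage * effect +
    noise, 0, 1); genotypes Hardy–Weinberg at the configured MAF; ages
    independent of genotype."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n, W = config.n_samples, config.n_windows

    dosages = rng.choice(3, size=n, p=config.hardy_weinberg).astype(float)
    ages = np.maximum(rng.normal(config.age_mean, config.age_sd, size=n), 1.0)
    status = np.zeros(n)
    status[rng.choice(n, size=config.n_cases, replace=False)] = 1.0

    eff = _per_window_effect(config)
    mean = config.baseline_mean + dosages[:, None] * eff[None, :]
    if config.age_effect:
        mean = mean + config.age_effect * (ages[:, None] - config.age_mean)
    if config.dmr_effect and config.dmr_window_ranges:
        for lo, hi in config.dmr_window_ranges:
            mean[:, lo - 1 : hi] += config.dmr_effect * status[:, None]

    if config.ar1_rho:
        rho = config.ar1_rho
        innov = rng.normal(0.0, config.noise_sd, size=(n, W))
        noise = np.empty_like(innov)
        noise[:, 0] = innov[:, 0]
        scale = np.sqrt(1 - rho**2)
        for j in range(1, W):
            noise[:, j] = rho * noise[:, j - 1] + scale * innov[:, j]
    else:
        noise = rng.normal(0.0, config.noise_sd, size=(n, W))

    usable = np.clip(mean + noise, 0.0, 1.0)

    grid = _build_grid(config, rng)
    scores = np.full((n, grid.n_windows), np.nan)
    scores[:, ~grid.mask] = usable
    sample_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    matrix = MethylationMatrix(grid, sample_ids, scores)
    genotypes = GenotypeTable(
        sample_ids, [config.snp_id], dosages[:, None], {config.snp_id: config.alleles}
    )
    metadata = SampleMetadata(sample_ids, status, ages)

    expected = config.baseline_mean + np.outer(np.arange(3.0), eff)
    lo, hi = config.hsm_window_range
    peak_region = Region(
        grid.chrom,
        matrix.grid.window_to_coords(lo).start,
        matrix.grid.window_to_coords(hi).end,
        label="hsm_peak",
    )
    truth = SimulationTruth(dosages, (lo, hi), peak_region, expected)
    return matrix, genotypes, metadata, truth


def simulate_null(
    config: SimulationConfig | None = None,
) -> tuple[MethylationMatrix, GenotypeTable, SampleMetadata, SimulationTruth]:
    """Same cohort with every genotype/status effect forced to zero."""
    config = config or SimulationConfig()
    return simulate_cohort(
        replace(config, effect_block=0.0, effect_peak=0.0, dmr_effect=0.0, age_effect=0.0)
    )


# ---------------------------------------------------------------------------
# pyrosequencing-style validation tables


@dataclass(frozen=True)
class PyroSite:
    """One assayed cytosine: SNP-dependent (its CpG only exists under the
    local CpG allele) or constitutive, with a baseline percent for the
    latter."""

    position: int
    snp_dependent: bool
    base_percent: float = 95.0
    noise_sd: float = 3.0


def simulate_pyro_table(
    config: SimulationConfig | None = None,
    sites: list[PyroSite] | None = None,
    n_samples: int = 80,
    n_discordant: int = 0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Per-sample per-site percent methylation with local CpG-SNP genotypes.

    SNP-dependent sites read ~100 * (local CpG-allele dosage)/2 plus noise
    (a non-CpG allele reads as unmethylated); constitutive sites are
    genotype-independent around their baseline.  ``n_discordant`` samples
    have a local genotype out of phase with the tag SNP (imperfect LD);
    their ids are returned as truth.  Returns (table, tag dosages,
    discordant sample ids); the table has columns sample, site, percent,
    local_dosage (NaN at constitutive sites).
    """
    config = config or SimulationConfig()
    if sites is None:
        sites = [
            PyroSite(52_379_190, True),
            PyroSite(52_379_221, False, 95.0),
            PyroSite(52_379_251, False, 96.7),
            PyroSite(52_379_254, False, 50.0),
        ]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tag = rng.choice(3, size=n_samples, p=config.hardy_weinberg).astype(float)
    sample_ids = [f"P{i:03d}" for i in range(1, n_samples + 1)]

    local = tag.copy()
    candidates = np.flatnonzero(tag > 0)
    if n_discordant > len(candidates):
        raise ValueError("not enough risk-allele carriers to make discordant")
    disc_idx = rng.choice(candidates, size=n_discordant, replace=False)
    for i in disc_idx:
        local[i] = tag[i] - 1  # lost one CpG allele relative to the tag phase
    discordant = [sample_ids[i] for i in sorted(disc_idx)]

    rows = []
    for site in sites:
        for i, sid in enumerate(sample_ids):
            if site.snp_dependent:
                pct = 100.0 * local[i] / 2.0 + rng.normal(0.0, site.noise_sd)
                ld = local[i]
            else:
                pct = site.base_percent + rng.normal(0.0, site.noise_sd)
                ld = np.nan
            rows.append(
                {
                    "sample": sid,
                    "site": site.position,
                    "percent": float(np.clip(pct, 0.0, 100.0)),
                    "local_dosage": ld,
                }
            )
    return pd.DataFrame(rows), tag, discordant
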