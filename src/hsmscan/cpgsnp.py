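"""Stage 4: the genetic architecture behind a haplotype-specific
methylation signal.

A SNP can create or abrogate a CpG dinucleotide when it is a YpG
polymorphism (alleles {C, T} immediately 5' of a G; IUPAC Y = C or T) or a
CpR polymorphism (alleles {A, G} immediately 3' of a C; R = G or A).  Under
exactly one of the two alleles the site is a CpG and hence able to be
methylated.  Because CpG is palindromic the call is strand-invariant:
checking both motifs on the given strand covers the reverse complement.

Polarising against the ancestral base distinguishes gains of
methylatability (the CpG allele is derived) from losses (the ancestral
state was the CpG).  The toolkit also clusters in-phase CpG-SNPs, counts a
haplotype's total CpG capability, computes D'/r^2 between phased loci, and
re-analyses bisulphite-pyrosequencing percent-methylation tables
(genotype stratification, re-stratification by the local CpG-SNP genotype,
and a screen for allele-specific methylation at non-polymorphic sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import kruskal_wallis
from .datamodel import SnpContext

__all__ = [
    "CpgSnpCall",
    "HaplotypeCpgCapability",
    "SiteMethylationSummary",
    "classify_cpg_snp",
    "ancestral_polarity",
    "ancestral_from_outgroups",
    "cluster_cpg_snps",
    "haplotype_cpg_capability",
    "ld_metrics",
    "site_genotype_methylation",
    "restratify_by_local_genotype",
    "mine_cpg_snp_stats",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CpgSnpCall:
    snp_id: str
    position: int
    motif_class: str  # "YpG" | "CpR" | "none"
    cpg_allele: str | None  # allele under which the CpG exists
    effect_vs_ancestral: str = "unknown"  # "gain" | "loss" | "none" | "unknown"

    @property
    def is_cpg_snp(self) -> bool:
        return self.motif_class != "none"


@dataclass(frozen=True)
class HaplotypeCpgCapability:
    haplotype: str
    reference_cpg_count: int
    gains: int
    losses: int

    @property
    def total(self) -> int:
        return self.reference_cpg_count + self.gains - self.losses


@dataclass
class SiteMethylationSummary:
    position: int
    snp_dependent: bool
    group_means: dict[str, float]  # genotype label -> mean percent
    group_n: dict[str, int]
    asm_flag: bool | None = None  # only for non-polymorphic sites
    asm_p: float = np.nan


def classify_cpg_snp(ctx: SnpContext) -> CpgSnpCall:
    """Classify a SNP as YpG, CpR or neither, on either strand.

    YpG: alleles {C, T} with G immediately 3' — the C allele forms CpG.
    CpR: alleles {A, G} with C immediately 5' — the G allele forms CpG.
    An N at the deciding flank base leaves the effect "unknown".
    """
    left = ctx.left_flank.upper()[-1]
    right = ctx.right_flank.upper()[0]
    alleles = ctx.alleles

    if alleles == frozenset("CT"):
        if right == "G":
            return CpgSnpCall(ctx.snp_id, ctx.position, "YpG", "C")
        if right == "N":
            return CpgSnpCall(ctx.snp_id, ctx.position, "none", None, "unknown")
    if alleles == frozenset("AG"):
        if left == "C":
            return CpgSnpCall(ctx.snp_id, ctx.position, "CpR", "G")
        if left == "N":
            return CpgSnpCall(ctx.snp_id, ctx.position, "none", None, "unknown")
    return CpgSnpCall(ctx.snp_id, ctx.position, "none", None, "none")


def ancestral_polarity(call: CpgSnpCall, ancestral: str | None, alleles: frozenset | None = None) -> str:
    """gain / loss / none / unknown of methylatability relative to the
    ancestral base.

    gain: the CpG allele is derived (ancestral carried the non-CpG state);
    loss: the ancestral base itself is the CpG allele, so the derived allele
    abrogates the site.
    """
    if not call.is_cpg_snp:
        return "none" if call.effect_vs_ancestral != "unknown" else "unknown"
    if ancestral is None or ancestral.upper() in ("N", "", "."):
        return "unknown"
    anc = ancestral.upper()
    if alleles is not None and anc not in alleles:
        warnings.warn(
            f"{call.snp_id}: ancestral base {anc} is not one of the segregating alleles",
            stacklevel=2,
        )
        return "unknown"
    return "loss" if anc == call.cpg_allele else "gain"


def ancestral_from_outgroups(bases: list[str]) -> str | None:
    """Ancestral base by unanimity across outgroup species (e.g. three
    primates); any disagreement or N returns None (unknown)."""
    clean = {b.upper() for b in bases if b}
    if len(clean) == 1 and clean <= set("ACGT"):
        return clean.pop()
    return None


def classify_with_polarity(ctx: SnpContext) -> CpgSnpCall:
    """Convenience: classification plus ancestral polarity in one call."""
    call = classify_cpg_snp(ctx)
    eff = ancestral_polarity(call, ctx.ancestral, ctx.alleles)
    return CpgSnpCall(call.snp_id, call.position, call.motif_class, call.cpg_allele, eff)


def cluster_cpg_snps(calls: list[CpgSnpCall], max_dist_bp: int = 75) -> list[list[CpgSnpCall]]:
    """Single-linkage clusters of calls whose positions lie within
    ``max_dist_bp`` (inclusive) of a neighbour, in genomic order."""
    if not calls:
        return []
    ordered = sorted(calls, key=lambda c: c.position)
    clusters = [[ordered[0]]]
    for call in ordered[1:]:
        if call.position - clusters[-1][-1].position <= max_dist_bp:
            clusters[-1].append(call)
        else:
            clusters.append([call])
    return clusters


def haplotype_cpg_capability(
    reference_cpg_count: int,
    phased_calls: list[tuple[CpgSnpCall, str, str]],
    haplotype: str = "",
) -> HaplotypeCpgCapability:
    """CpG capability of one haplotype.

    ``phased_calls``: (call, allele on this haplotype, reference-sequence
    base at the SNP).  A gain is a haplotype allele equal to the CpG allele
    where the reference base is not; a loss is a reference CpG the haplotype
    allele abrogates.
    """
    gains = losses = 0
    for call, hap_allele, ref_allele in phased_calls:
        if not call.is_cpg_snp:
            continue
        hap_allele, ref_allele = hap_allele.upper(), ref_allele.upper()
        if hap_allele not in (call.cpg_allele, *_other_alleles(call)):
            raise ValueError(
                f"{call.snp_id}: haplotype allele {hap_allele!r} not a segregating allele"
            )
        if hap_allele == call.cpg_allele and ref_allele != call.cpg_allele:
            gains += 1
        elif ref_allele == call.cpg_allele and hap_allele != call.cpg_allele:
            losses += 1
    return HaplotypeCpgCapability(haplotype, reference_cpg_count, gains, losses)


def _other_alleles(call: CpgSnpCall) -> tuple[str, ...]:
    return ("T", "C") if call.motif_class == "YpG" else ("A", "G")


def ld_metrics(hapA: np.ndarray, hapB: np.ndarray) -> tuple[float, float]:
    """D' and r^2 between two loci from phased binary haplotype vectors
    (one entry per haplotype copy, 1 = minor/derived allele)."""
    hapA = np.asarray(hapA, dtype=float)
    hapB = np.asarray(hapB, dtype=float)
    if hapA.shape != hapB.shape or hapA.ndim != 1:
        raise ValueError("haplotype vectors must be 1-D and equal length")
    pA, pB = hapA.mean(), hapB.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus")
    pAB = (hapA * hapB).mean()
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D**2 / (pA * (1 - pA) * pB * (1 - pB))
    # clamp float round-off at the theoretical bounds
    return float(min(dprime, 1.0)), float(min(r2, 1.0))


# ---------------------------------------------------------------------------
# pyrosequencing-table re-analysis

_GENOTYPE_LABELS = {0.0: "00", 1.0: "01", 2.0: "02"}


def site_genotype_methylation(
    pyro: pd.DataFrame,
    dosages: np.ndarray,
    site_snp_dependence: dict[int, bool],
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> list[SiteMethylationSummary]:
    """Per-site, per-genotype mean percent methylation.

    ``pyro`` has columns (sample, site, percent); ``dosages`` aligns with the
    unique samples in order of first appearance.  For constitutive
    (non-SNP-dependent) sites an ASM flag is raised when a Kruskal–Wallis
    test across genotype groups rejects at ``alpha`` (optionally Bonferroni
    over the number of constitutive sites).
    """
    samples = list(dict.fromkeys(pyro["sample"]))
    dosages = np.asarray(dosages, dtype=float)
    if len(samples) != len(dosages):
        raise ValueError("dosage vector must align with the pyro table's samples")
    dose_of = dict(zip(samples, dosages))
    sites = sorted(pyro["site"].unique())
    n_const = sum(1 for s in sites if not site_snp_dependence.get(int(s), False))
    thr = alpha / max(1, n_const) if bonferroni else alpha

    out = []
    for site in sites:
        sub = pyro[pyro["site"] == site]
        vals = sub["percent"].to_numpy(float)
        dos = np.array([dose_of[s] for s in sub["sample"]])
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError(f"site {site}: percent outside [0, 100]")
        means, ns = {}, {}
        for d, label in _GENOTYPE_LABELS.items():
            sel = dos == d
            if sel.any():
                means[label] = float(vals[sel].mean())
                ns[label] = int(sel.sum())
        dep = bool(site_snp_dependence.get(int(site), False))
        summ = SiteMethylationSummary(int(site), dep, means, ns)
        if not dep:
            if len(means) >= 2:
                _, p = kruskal_wallis(vals, dos)
                summ.asm_p = p
                summ.asm_flag = bool(p < thr)
            else:
                summ.asm_flag = None
        out.append(summ)
    return out


def restratify_by_local_genotype(
    pyro: pd.DataFrame,
    tag_dosages: np.ndarray,
    site: int,
) -> tuple[list[str], dict[str, float]]:
    """Find samples whose local CpG-SNP genotype disagrees with the phase the
    tag SNP implies, and recompute group means on concordant samples only.

    ``pyro`` must carry a ``local_dosage`` column (CpG-allele count read from
    the sequence at the site).  Perfect LD implies local_dosage ==
    tag dosage; any mismatch is discordant.
    """
    samples = list(dict.fromkeys(pyro["sample"]))
    tag_dosages = np.asarray(tag_dosages, dtype=float)
    dose_of = dict(zip(samples, tag_dosages))
    sub = pyro[pyro["site"] == site]
    if "local_dosage" not in sub.columns:
        raise ValueError("pyro table lacks a local_dosage column")
    discordant = [
        str(s)
        for s, local in zip(sub["sample"], sub["local_dosage"])
        if np.isfinite(local) and local != dose_of[s]
    ]
    keep = sub[~sub["sample"].isin(discordant)]
    means: dict[str, float] = {}
    for d, label in _GENOTYPE_LABELS.items():
        sel = keep[[dose_of[s] == d for s in keep["sample"]]]
        if len(sel):
            means[label] = float(sel["percent"].mean())
        else:
            means[label] = float("nan")
    if keep.empty:
        warnings.warn("all samples discordant — means undefined", stacklevel=2)
    return discordant, means


def mine_cpg_snp_stats(snp_table: list[SnpContext], max_dist_bp: int = 75) -> dict[str, float]:
    """Summary fractions over a SNP table: SNPs with CpG potential (either
    allele yields a CpG), ancestral gains of methylatability, and gains
    lying within ``max_dist_bp`` of another gain.  Denominator is the full
    table in each case."""
    if not snp_table:
        raise ValueError("empty SNP table")
    n = len(snp_table)
    calls = [classify_with_polarity(ctx) for ctx in snp_table]
    n_cpg = sum(c.is_cpg_snp for c in calls)
    gains = [c for c in calls if c.effect_vs_ancestral == "gain"]
    clustered = 0
    if gains:
        for cluster in cluster_cpg_snps(gains, max_dist_bp):
            if len(cluster) > 1:
                clustered += len(cluster)
    return {
        "fraction_cpg_site": n_cpg / n,
        "fraction_gain": len(gains) / n,
        "fraction_clustered_gain": clustered / n,
    }
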