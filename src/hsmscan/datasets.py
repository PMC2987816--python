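"""Published worked-example inputs for the FTO haplotype-specific
methylation analysis (hg18 coordinates).

These are the printed inputs of the original study — the narrow-peak and
broad-peak intervals, the three CpG-creating/abrogating SNPs of the 900-bp
peak with their flanking contexts and primate-derived ancestral states, and
the genotype-stratified pyrosequencing percentages — so the genetics
toolkit's worked examples can be recomputed from first principles without
any download.
"""

from __future__ import annotations

import pandas as pd

from .datamodel import Region, SnpContext

__all__ = [
    "fto_ld_block",
    "fto_broad_peak",
    "fto_narrow_peak",
    "fto_narrow_peak_cpg_snps",
    "FTO_REFERENCE_CPG_COUNT",
    "fto_pyro_table5",
]

#: CpG sites in the reference sequence of the 900-bp narrow peak.
FTO_REFERENCE_CPG_COUNT = 7


def fto_ld_block() -> Region:
    """The 46 kb FTO susceptibility LD block tagged by rs8050136."""
    return Region("chr16", 52_357_008, 52_402_988, "FTO_LD_block")


def fto_broad_peak() -> Region:
    """The 60-window (7.7 kb after repeat exclusion) broad peak."""
    return Region("chr16", 52_371_700, 52_379_399, "broad_peak_w60")


def fto_narrow_peak() -> Region:
    """The 9-window (900 bp) narrow peak."""
    return Region("chr16", 52_378_500, 52_379_399, "narrow_peak_w9")


def fto_narrow_peak_cpg_snps() -> list[SnpContext]:
    """The three CpG-creating/abrogating SNPs inside the narrow peak, with
    their published flank contexts and ancestral bases (unanimous across
    chimpanzee, orangutan and macaque)."""
    return [
        SnpContext(
            snp_id="rs7206629",
            chrom="chr16",
            position=52_378_914,
            left_flank="TTGGT",
            allele_a="C",
            allele_b="T",
            right_flank="GAAGT",
            ancestral="C",
            frequencies={"EUR_minor": 0.391},
        ),
        SnpContext(
            snp_id="rs7202116",
            chrom="chr16",
            position=52_379_116,
            left_flank="TAAAC",
            allele_a="A",
            allele_b="G",
            right_flank="TCTTT",
            ancestral="A",
            frequencies={"EUR_minor": 0.391},
        ),
        SnpContext(
            snp_id="rs7202296",
            chrom="chr16",
            position=52_379_191,
            left_flank="AAGCC",
            allele_a="A",
            allele_b="G",
            right_flank="ATAAA",
            ancestral="A",
            frequencies={"EUR_minor": 0.391},
        ),
    ]


def fto_pyro_table5() -> pd.DataFrame:
    """Published genotype-stratified percent methylation at the four
    narrow-peak cytosines (tag-SNP genotype groups AA/AC/CC; site 52379190
    is the rs7202296-dependent cytosine)."""
    return pd.DataFrame(
        {
            "site": [52_379_190, 52_379_221, 52_379_251, 52_379_254],
            "snp_dependent": [True, False, False, False],
            "AA": [87.0, 95.1, 96.7, 49.6],
            "AC": [55.7, 95.5, 97.0, 51.6],
            "CC": [11.5, 95.1, 96.6, 49.9],
        }
    )
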