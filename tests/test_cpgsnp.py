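"""CpG-creating-SNP genetics: classification, polarity, clustering,
haplotype capability, LD metrics and pyro-table re-analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsmscan.cpgsnp import (
    CpgSnpCall,
    ancestral_from_outgroups,
    ancestral_polarity,
    classify_cpg_snp,
    classify_with_polarity,
    cluster_cpg_snps,
    haplotype_cpg_capability,
    ld_metrics,
    mine_cpg_snp_stats,
    restratify_by_local_genotype,
    reverse_complement,
    site_genotype_methylation,
)
from hsmscan.datamodel import SnpContext
from hsmscan.datasets import FTO_REFERENCE_CPG_COUNT, fto_narrow_peak_cpg_snps
from hsmscan.simulate import PyroSite, SimulationConfig, simulate_pyro_table

SNPS = {c.snp_id: c for c in fto_narrow_peak_cpg_snps()}


class TestClassification:
    @pytest.mark.parametrize(
        "snp_id, motif, cpg_allele",
        [("rs7206629", "YpG", "C"), ("rs7202116", "CpR", "G"), ("rs7202296", "CpR", "G")],
    )
    def test_published_narrow_peak_snps(self, snp_id, motif, cpg_allele):
        call = classify_cpg_snp(SNPS[snp_id])
        assert call.motif_class == motif
        assert call.cpg_allele == cpg_allele

    def test_no_cpg_possible(self):
        ctx = SnpContext("x", 100, "TTTTT", "A", "G", "TTTTT")
        assert not classify_cpg_snp(ctx).is_cpg_snp

    def test_n_at_deciding_base_is_unknown(self):
        ctx = SnpContext("x", 100, "TTTTT", "C", "T", "NAAAA")
        call = classify_cpg_snp(ctx)
        assert not call.is_cpg_snp and call.effect_vs_ancestral == "unknown"

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        left=st.text("ACGT", min_size=1, max_size=6),
        right=st.text("ACGT", min_size=1, max_size=6),
        alleles=st.sampled_from(["CT", "AG", "AC", "AT", "CG", "GT"]),
    )
    def test_strand_invariance(self, left, right, alleles):
        """CpG is palindromic: the reverse-complement context gives the same
        motif-containing verdict with the complementary CpG allele."""
        fwd = SnpContext("f", 1, left, alleles[0], alleles[1], right)
        rev = SnpContext(
            "r",
            1,
            reverse_complement(right),
            reverse_complement(alleles[0]),
            reverse_complement(alleles[1]),
            reverse_complement(left),
        )
        a, b = classify_cpg_snp(fwd), classify_cpg_snp(rev)
        assert a.is_cpg_snp == b.is_cpg_snp
        if a.is_cpg_snp:
            assert b.cpg_allele == reverse_complement(a.cpg_allele)


class TestPolarity:
    def test_published_gain_loss_pattern(self):
        """Two of the three peak SNPs gained methylatability from the
        ancestral CpA state; rs7206629's ancestral state is the CpG."""
        effects = {s: classify_with_polarity(c).effect_vs_ancestral for s, c in SNPS.items()}
        assert effects == {"rs7206629": "loss", "rs7202116": "gain", "rs7202296": "gain"}

    def test_missing_ancestral_unknown(self):
        call = classify_cpg_snp(SNPS["rs7202116"])
        assert ancestral_polarity(call, None) == "unknown"

    def test_ancestral_not_segregating_warns(self):
        call = classify_cpg_snp(SNPS["rs7202116"])
        with pytest.warns(UserWarning):
            assert ancestral_polarity(call, "T", frozenset("AG")) == "unknown"

    def test_outgroup_unanimity(self):
        assert ancestral_from_outgroups(["A", "A", "A"]) == "A"
        assert ancestral_from_outgroups(["A", "C", "A"]) is None
        assert ancestral_from_outgroups(["N", "N"]) is None


def brute_force_single_linkage(positions, max_dist):
    """Union-find over the full pairwise distance matrix."""
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if abs(positions[i] - positions[j]) <= max_dist:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(positions)):
        groups.setdefault(find(i), set()).add(positions[i])
    return {frozenset(g) for g in groups.values()}


class TestClustering:
    def _calls(self, positions):
        return [CpgSnpCall(f"s{i}", p, "CpR", "G") for i, p in enumerate(positions)]

    def test_published_pair_is_75_bp_apart_and_clusters(self):
        a, b = SNPS["rs7202116"], SNPS["rs7202296"]
        assert b.position - a.position == 75
        clusters = cluster_cpg_snps(self._calls([a.position, b.position]), 75)
        assert len(clusters) == 1

    def test_beyond_threshold_splits(self):
        assert len(cluster_cpg_snps(self._calls([100, 300]), 75)) == 2

    def test_chain_is_single_linkage(self):
        clusters = cluster_cpg_snps(self._calls([0, 75, 150]), 75)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            positions = sorted(set(rng.integers(0, 2000, size=rng.integers(2, 50)).tolist()))
            got = {
                frozenset(c.position for c in cl)
                for cl in cluster_cpg_snps(self._calls(positions), 75)
            }
            assert got == brute_force_single_linkage(positions, 75)


class TestCapability:
    def _phased(self, on_risk=True):
        calls = [classify_with_polarity(c) for c in SNPS.values()]
        ref = {"rs7206629": "T", "rs7202116": "A", "rs7202296": "A"}
        other = {"YpG": {"C": "T", "T": "C"}, "CpR": {"A": "G", "G": "A"}}
        out = []
        for c in calls:
            hap = c.cpg_allele if on_risk else other[c.motif_class][c.cpg_allele]
            out.append((c, hap, ref[c.snp_id]))
        return out

    def test_risk_haplotype_has_ten_sites_reference_seven(self):
        risk = haplotype_cpg_capability(FTO_REFERENCE_CPG_COUNT, self._phased(True), "risk")
        alt = haplotype_cpg_capability(FTO_REFERENCE_CPG_COUNT, self._phased(False), "alt")
        assert (risk.gains, risk.losses, risk.total) == (3, 0, 10)
        assert alt.total == 7

    def test_gain_loss_cancellation(self):
        call_gain = CpgSnpCall("g", 1, "CpR", "G")
        call_loss = CpgSnpCall("l", 2, "YpG", "C")
        cap = haplotype_cpg_capability(5, [(call_gain, "G", "A"), (call_loss, "T", "C")])
        assert (cap.gains, cap.losses, cap.total) == (1, 1, 5)

    def test_capability_difference_identity(self):
        a = haplotype_cpg_capability(7, self._phased(True))
        b = haplotype_cpg_capability(7, self._phased(False))
        assert a.total - b.total == (a.gains - b.gains) - (a.losses - b.losses)

    def test_unknown_allele_rejected(self):
        call = CpgSnpCall("g", 1, "CpR", "G")
        with pytest.raises(ValueError):
            haplotype_cpg_capability(5, [(call, "T", "A")])


class TestLdMetrics:
    def test_perfect_ld(self):
        h = np.array([1, 0, 1, 0, 1, 1, 0, 0], float)
        assert ld_metrics(h, h) == pytest.approx((1.0, 1.0))

    def test_hand_fixture(self):
        """Counts AB:3 Ab:1 aB:1 ab:3 over 8 haplotypes: D = 1/8,
        Dmax = 1/4, so D' = 0.5 and r2 = 0.25."""
        A = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        B = np.array([1, 1, 1, 0, 1, 0, 0, 0], float)
        dprime, r2 = ld_metrics(A, B)
        assert (dprime, r2) == pytest.approx((0.5, 0.25))

    def test_independent_loci_r2_near_zero(self):
        rng = np.random.default_rng(1)
        A = (rng.random(10_000) < 0.4).astype(float)
        B = (rng.random(10_000) < 0.6).astype(float)
        dprime, r2 = ld_metrics(A, B)
        assert r2 < 0.002

    def test_bounds_property(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            A = (rng.random(40) < rng.uniform(0.1, 0.9)).astype(float)
            B = (rng.random(40) < rng.uniform(0.1, 0.9)).astype(float)
            if A.mean() in (0, 1) or B.mean() in (0, 1):
                continue
            dprime, r2 = ld_metrics(A, B)
            assert -1e-12 <= r2 <= dprime + 1e-12 <= 1 + 1e-12

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_metrics(np.ones(8), np.array([1, 0] * 4, float))


class TestPyroReanalysis:
    def _table(self, n=40, n_discordant=0, seed=13, noise=1e-9):
        sites = [PyroSite(52_379_190, True, noise_sd=noise), PyroSite(52_379_221, False, 95.0, noise)]
        return simulate_pyro_table(
            SimulationConfig(seed=seed), sites, n_samples=n, n_discordant=n_discordant, seed=seed
        )

    def test_noiseless_dosage_gradient(self):
        table, tag, _ = self._table()
        summaries = site_genotype_methylation(
            table, tag, {52_379_190: True, 52_379_221: False}
        )
        dep = next(s for s in summaries if s.snp_dependent)
        for label, expected in (("02", 100.0), ("01", 50.0), ("00", 0.0)):
            if label in dep.group_means:
                assert dep.group_means[label] == pytest.approx(expected, abs=1e-4)

    def test_constitutive_site_not_flagged(self):
        table, tag, _ = self._table()
        summaries = site_genotype_methylation(table, tag, {52_379_190: True, 52_379_221: False})
        const = next(s for s in summaries if not s.snp_dependent)
        assert const.asm_flag is False

    def test_asm_shift_flagged(self):
        """A +20-point shift in risk homozygotes at a non-polymorphic site
        is picked up by the per-site Kruskal–Wallis screen."""
        rng = np.random.default_rng(3)
        n = 80
        tag = rng.choice(3, size=n, p=(0.33, 0.49, 0.18)).astype(float)
        pct = np.clip(rng.normal(70, 3, n) + 20 * (tag == 2), 0, 100)
        table = pd.DataFrame(
            {"sample": [f"P{i}" for i in range(n)], "site": 1, "percent": pct}
        )
        (summ,) = site_genotype_methylation(table, tag, {1: False})
        assert summ.asm_flag is True

    def test_restratify_recovers_injected_discordants(self):
        table, tag, disc = self._table(n=80, n_discordant=2)
        found, means = restratify_by_local_genotype(table, tag, 52_379_190)
        assert sorted(found) == sorted(disc)
        # concordant risk homozygotes read ~100% once discordants are removed
        assert means["02"] == pytest.approx(100.0, abs=1e-4)

    def test_concordant_cohort_unchanged(self):
        table, tag, _ = self._table(n=40)
        found, means = restratify_by_local_genotype(table, tag, 52_379_190)
        assert found == []


class TestMineStats:
    def test_published_three_snp_table(self):
        stats = mine_cpg_snp_stats(fto_narrow_peak_cpg_snps())
        assert stats["fraction_cpg_site"] == pytest.approx(1.0)
        assert stats["fraction_gain"] == pytest.approx(2 / 3)
        assert stats["fraction_clustered_gain"] == pytest.approx(2 / 3)

    def test_no_cpg_potential(self):
        table = [SnpContext(f"s{i}", 100 * i + 1, "TTTTT", "A", "T", "TTTTT") for i in range(5)]
        stats = mine_cpg_snp_stats(table)
        assert set(stats.values()) == {0.0}

    def test_constructed_composition(self):
        """100 SNPs: 40 CpG-class, 10 of them ancestral gains, 2 of the gains
        within 75 bp of each other -> fractions 0.40 / 0.10 / 0.02."""
        table = []
        # exactly one gain pair (g0, g1) lies within 75 bp
        gain_positions = [10_000, 10_050] + [20_000 + 1_000 * i for i in range(8)]
        for i, p in enumerate(gain_positions):
            table.append(SnpContext(f"g{i}", p, "CCCCC", "A", "G", "TTTTT", ancestral="A"))
        for i in range(30):  # CpG-class losses (ancestral is the CpG allele)
            table.append(
                SnpContext(f"l{i}", 100_000 + 500 * i, "CCCCC", "A", "G", "TTTTT", ancestral="G")
            )
        for i in range(60):  # no CpG potential
            table.append(
                SnpContext(f"n{i}", 200_000 + 500 * i, "TTTTT", "A", "T", "TTTTT", ancestral="A")
            )
        stats = mine_cpg_snp_stats(table)
        assert stats["fraction_cpg_site"] == pytest.approx(0.40)
        assert stats["fraction_gain"] == pytest.approx(0.10)
        assert stats["fraction_clustered_gain"] == pytest.approx(0.02)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mine_cpg_snp_stats([])
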