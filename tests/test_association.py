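"""Block-level association: loads, Kruskal–Wallis, dosage regression and
permutation empirical p-values."""

import numpy as np
import pytest
from scipy import stats
from sympy.utilities.iterables import multiset_permutations

from hsmscan._stats import rowwise_kruskal, rowwise_ols
from hsmscan.association import (
    block_scan,
    genotype_regression,
    kruskal_wallis,
    methylation_load,
    permutation_pvalue,
    results_table,
)
from hsmscan.datamodel import GenomicWindowGrid, MethylationMatrix, Region

from conftest import full_block


def enumerate_kw_pvalue(values, groups):
    """Exact permutation p for the KW statistic: fraction of all distinct
    group assignments with H >= observed (ties included)."""
    h_obs, _ = kruskal_wallis(values, groups)
    count = total = 0
    for perm in multiset_permutations(list(groups)):
        h, _ = kruskal_wallis(values, np.array(perm, float))
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


class TestMethylationLoad:
    def test_constant_track(self):
        grid = GenomicWindowGrid("chr1", 1, 4, 100)
        m = MethylationMatrix(grid, ["a", "b"], np.full((2, 4), 0.5))
        np.testing.assert_allclose(methylation_load(m, Region("chr1", 1, 400)), 0.5)

    def test_masked_window_excluded_from_mean(self):
        grid = GenomicWindowGrid("chr1", 1, 3, 100, mask=np.array([0, 1, 0], bool))
        m = MethylationMatrix(grid, ["a"], np.array([[0.2, 0.4, 0.9]]))
        assert methylation_load(m, Region("chr1", 1, 300))[0] == pytest.approx(0.55)

    def test_fully_masked_region_errors(self):
        grid = GenomicWindowGrid("chr1", 1, 3, 100, mask=np.array([0, 1, 0], bool))
        m = MethylationMatrix(grid, ["a"], np.array([[0.2, 0.4, 0.9]]))
        with pytest.raises(ValueError):
            methylation_load(m, Region("chr1", 101, 200))

    def test_partition_additivity(self):
        """The load of a region is the unmasked-window-count weighted mean of
        the loads of a partition of it."""
        grid = GenomicWindowGrid("chr1", 1, 10, 100, mask=np.arange(10) % 3 == 0)
        rng = np.random.default_rng(0)
        m = MethylationMatrix(grid, ["a", "b"], rng.random((2, 10)))
        whole = methylation_load(m, Region("chr1", 1, 1000))
        left = methylation_load(m, Region("chr1", 1, 500))
        right = methylation_load(m, Region("chr1", 501, 1000))
        nl = grid.windows_in_region(Region("chr1", 1, 500)).size
        nr = grid.windows_in_region(Region("chr1", 501, 1000)).size
        np.testing.assert_allclose(whole, (nl * left + nr * right) / (nl + nr))


class TestKruskalWallis:
    def test_three_group_hand_fixture(self):
        """Midranks of {1,2,3},{4,5,6},{7,8,9} give H = 7.2, p = exp(-3.6)."""
        h, p = kruskal_wallis(np.arange(1.0, 10.0), np.repeat([0, 1, 2], 3))
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(0.02732372, abs=1e-6)

    def test_identical_values_convention(self):
        h, p = kruskal_wallis(np.ones(6), np.repeat([0, 1], 3))
        assert (h, p) == (0.0, 1.0)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis(np.arange(4.0), np.zeros(4))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        v = np.round(rng.random(30), 1)  # force ties
        g = rng.integers(0, 3, 30).astype(float)
        h, p = kruskal_wallis(v, g)
        h2, p2 = stats.kruskal(*(v[g == k] for k in range(3)))
        assert (h, p) == pytest.approx((h2, p2))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.random(20)
        g = rng.integers(0, 3, 20).astype(float)
        assert kruskal_wallis(v, g) == pytest.approx(kruskal_wallis(np.exp(3 * v), g))

    def test_rowwise_matches_scalar(self):
        rng = np.random.default_rng(3)
        V = np.round(rng.random((8, 12)), 1)
        g = np.repeat([0, 1, 2], 4).astype(float)
        H, P = rowwise_kruskal(V, g)
        for i in range(8):
            h, p = kruskal_wallis(V[i], g)
            assert (H[i], P[i]) == pytest.approx((h, p))

    def test_permutation_p_converges_to_exact_enumeration(self):
        """At n = 8 the shuffled-genotype empirical p approaches the
        exhaustive-assignment p (the chi-square p is only asymptotic)."""
        values = np.array([0.1, 0.3, 0.2, 0.8, 0.9, 0.7, 0.5, 0.4])
        groups = np.array([0, 0, 0, 1, 1, 1, 2, 2], float)
        exact = enumerate_kw_pvalue(values, groups)
        p_emp = permutation_pvalue(values, groups, "kw", n_perm=20_000, seed=0)
        assert p_emp == pytest.approx(exact, abs=0.01)


class TestRegression:
    def test_perfect_linear_fit(self):
        d = np.repeat([0.0, 1.0, 2.0], 2)
        loads = 0.1 + 0.1 * d
        slope, p, _ = genotype_regression(loads, d)
        assert slope == pytest.approx(0.1, abs=1e-12)
        assert p < 1e-12

    def test_matches_closed_form_normal_equations(self):
        """Two-regressor OLS on a 6-sample fixture against (X'X)^-1 X'y."""
        d = np.array([0, 0, 1, 1, 2, 2], float)
        age = np.array([31.0, 44.0, 35.0, 39.0, 28.0, 50.0])
        y = np.array([0.48, 0.51, 0.52, 0.50, 0.55, 0.56])
        slope, lr_p, age_p = genotype_regression(y, d, age)
        X = np.column_stack([np.ones(6), d, age])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (6 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        t = beta / se
        assert slope == pytest.approx(beta[1], abs=1e-10)
        assert lr_p == pytest.approx(2 * stats.t.sf(abs(t[1]), 3), abs=1e-10)
        assert age_p == pytest.approx(2 * stats.t.sf(abs(t[2]), 3), abs=1e-10)

    def test_rowwise_ols_matches_single_fits(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, 25).astype(float)
        age = rng.normal(37, 6.6, 25)
        Y = rng.random((6, 25))
        slopes, tvals, ps = rowwise_ols(Y, d, age)
        for i in range(6):
            s, p, _ = genotype_regression(Y[i], d, age)
            assert slopes[i] == pytest.approx(s, abs=1e-10)
            assert ps[i] == pytest.approx(p, abs=1e-10)

    def test_degenerate_dosage_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            genotype_regression(np.random.default_rng(0).random(6), np.ones(6))

    def test_collinear_covariate_errors(self):
        d = np.repeat([0.0, 1.0, 2.0], 2)
        with pytest.raises(ValueError, match="collinear"):
            genotype_regression(0.1 * d + 0.4, d, age=2 * d)


class TestPermutationP:
    def test_strong_separation_attains_enumeration_floor(self):
        """Loads 0.1,0.1,0.9,0.9 split by dosage 0/2: only 6 distinct
        assignments exist, 2 of which reproduce the perfect split, so the
        attainable p is ~1/3 for KW — and the observed split must sit at the
        extreme."""
        values = np.array([0.1, 0.1, 0.9, 0.9])
        groups = np.array([0, 0, 2, 2], float)
        exact = enumerate_kw_pvalue(values, groups)
        p = permutation_pvalue(values, groups, "kw", n_perm=10_000, seed=1)
        assert p == pytest.approx(exact, abs=0.02)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(5)
        v, g = rng.random(20), rng.integers(0, 3, 20).astype(float)
        a = permutation_pvalue(v, g, "lr", 500, seed=9)
        b = permutation_pvalue(v, g, "lr", 500, seed=9)
        assert a == b

    def test_reorder_invariance_of_tests(self):
        rng = np.random.default_rng(6)
        v, g = rng.random(20), rng.integers(0, 3, 20).astype(float)
        order = rng.permutation(20)
        assert kruskal_wallis(v, g) == pytest.approx(kruskal_wallis(v[order], g[order]))
        assert genotype_regression(v, g)[:2] == pytest.approx(
            genotype_regression(v[order], g[order])[:2]
        )

    def test_low_n_perm_warns(self):
        rng = np.random.default_rng(7)
        with pytest.warns(UserWarning):
            permutation_pvalue(rng.random(10), rng.integers(0, 3, 10).astype(float), "lr", 50)


class TestBlockScan:
    def test_single_region_bonferroni_equals_raw(self, default_cohort):
        m, g, meta, truth = default_cohort
        region = full_block(m)
        region = Region(region.chrom, region.start, region.end, "FTO")
        res = block_scan(m, g, [region], {"FTO": "rs8050136"}, meta, n_perm=200, seed=0)
        assert len(res) == 1
        assert res[0].lr_p_bonferroni == pytest.approx(res[0].lr_p)
        assert sum(res[0].n_per_group) == m.n_samples
        df = results_table(res)
        assert {"chrom", "start", "end", "snp", "mean_00", "kw_p", "lr_p", "perm_p"} <= set(
            df.columns
        )

    def test_region_without_tag_snp_skipped(self, default_cohort):
        m, g, meta, _ = default_cohort
        region = Region(m.grid.chrom, m.grid.start, m.grid.start + 999, "orphan")
        assert block_scan(m, g, [region], {}, meta, n_perm=200) == []
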