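import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enerlim import convergence as cv


def enumerate_intersection_pmf(sizes, n_genes, k):
    """Exhaustive enumeration over all subset tuples (oracle for tiny genomes)."""
    genes = range(n_genes)
    hits = total = 0
    subset_lists = [list(itertools.combinations(genes, s)) for s in sizes]
    for combo in itertools.product(*subset_lists):
        inter = set(combo[0])
        for c in combo[1:]:
            inter &= set(c)
        total += 1
        hits += len(inter) == k
    return hits / total


class TestIntersectionPmf:
    def test_two_sets_of_two_in_four_full_overlap(self):
        assert cv.intersection_pmf([2, 2], 4, 2) == pytest.approx(1 / 6)
        assert cv.intersection_pmf([2, 2], 4, 2) == pytest.approx(
            enumerate_intersection_pmf([2, 2], 4, 2)
        )

    def test_two_sets_of_two_in_four_single_overlap(self):
        assert cv.intersection_pmf([2, 2], 4, 1) == pytest.approx(2 / 3)

    def test_k_beyond_smallest_set_is_zero(self):
        assert cv.intersection_pmf([2, 3], 10, 3) == 0.0

    @pytest.mark.parametrize("sizes,n_genes", [([2, 2], 5), ([3, 2], 6), ([2, 2, 2], 5)])
    def test_pmf_sums_to_one(self, sizes, n_genes):
        total = sum(cv.intersection_pmf(sizes, n_genes, k) for k in range(min(sizes) + 1))
        assert total == pytest.approx(1.0)

    def test_symmetric_under_size_exchange(self):
        for k in range(3):
            assert cv.intersection_pmf([2, 3], 7, k) == pytest.approx(
                cv.intersection_pmf([3, 2], 7, k)
            )

    def test_three_sets_match_enumeration(self):
        sizes, n = [3, 2, 2], 6
        for k in range(3):
            assert cv.intersection_pmf(sizes, n, k, method="exact") == pytest.approx(
                enumerate_intersection_pmf(sizes, n, k)
            )


class TestJaccardTest:
    def test_identical_sets_hit_convergence_floor(self):
        genes = set(range(5))
        res = cv.jaccard_test(genes, genes, 1000, n_sim=99, seed=0)
        assert res.p_convergence == pytest.approx(1 / 100)
        assert res.jaccard == 1.0

    def test_empty_set_is_uninformative(self):
        """An empty enriched set forces J = 0 under every null draw: both p = 1."""
        res = cv.jaccard_test(set(), {2, 3}, 4, n_sim=199, seed=0)
        assert res.jaccard == 0.0
        assert res.p_divergence == 1.0 and res.p_convergence == 1.0

    def test_disjoint_sets_divergence_p_matches_zero_overlap_mass(self):
        """For disjoint sets, p(divergence) estimates P(no overlap) under the null."""
        res = cv.jaccard_test({0, 1}, {2, 3}, 4, n_sim=1999, seed=0)
        assert res.jaccard == 0.0
        p0 = cv.intersection_pmf([2, 2], 4, 0)  # = 1/6
        assert res.p_divergence == pytest.approx(p0, abs=3 * np.sqrt(p0 * (1 - p0) / 2000))

    def test_null_mean_matches_hypergeometric_expectation(self):
        s1, s2, n_genes, n_sim = 6, 4, 30, 4000
        res = cv.jaccard_test(set(range(s1)), set(range(s2)), n_genes, n_sim=n_sim, seed=3)
        expected = sum(
            cv.intersection_pmf([s1, s2], n_genes, k) * k / (s1 + s2 - k)
            for k in range(min(s1, s2) + 1)
        )
        assert res.null_mean == pytest.approx(expected, abs=3 * res.null_sd / np.sqrt(n_sim))


class TestFixedMarginRandomize:
    def test_margins_preserved_every_draw(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(3, size=(6, 3))
        for _ in range(50):
            out = cv.fixed_margin_randomize(mat, rng)
            np.testing.assert_array_equal(out.sum(axis=0), mat.sum(axis=0))
            np.testing.assert_array_equal(out.sum(axis=1), mat.sum(axis=1))

    def test_zero_row_unchanged(self):
        mat = np.array([[3, 2], [0, 0], [1, 4]])
        out = cv.fixed_margin_randomize(mat, np.random.default_rng(1))
        np.testing.assert_array_equal(out[1], [0, 0])

    def test_two_by_two_cell_follows_hypergeometric(self):
        """Cell (0,0) over many draws matches the hypergeometric pmf (GOF)."""
        mat = np.array([[5, 3], [2, 6]])
        rng = np.random.default_rng(0)
        n_draws = 20_000
        batch = cv._fixed_margin_randomize_two_col_batch(mat, n_draws, rng)
        values = batch[:, 0, 0]
        support = np.arange(0, 8)  # cell (0,0) ~ Hypergeom(M=16, K=7, n=8)
        pmf = stats.hypergeom.pmf(support, 16, 7, 8)
        observed = np.bincount(values, minlength=support.size).astype(float)
        res = stats.chisquare(observed, pmf * n_draws)
        assert res.pvalue > 0.01

    def test_empirically_uniform_on_2x3_against_enumeration(self):
        """Table frequencies on a 2x3 instance match multivariate hypergeometric weights."""
        mat = np.array([[2, 1, 1], [1, 2, 0]])
        rng = np.random.default_rng(5)
        counts = {}
        n_draws = 20_000
        for _ in range(n_draws):
            out = cv.fixed_margin_randomize(mat, rng)
            counts[tuple(out.flatten())] = counts.get(tuple(out.flatten()), 0) + 1
        # exact probabilities: product of multinomials / multinomial of totals
        from math import comb, prod

        def table_weight(flat):
            t = np.array(flat).reshape(2, 3)
            row = [prod(comb(int(r.sum()), int(x)) for x in r[:-1]) for r in t]
            # multivariate hypergeometric over tables with fixed margins:
            # weight proportional to prod_j colsum_j! / prod_ij a_ij!
            from math import factorial

            w = 1.0
            for j in range(3):
                w *= factorial(int(t[:, j].sum()))
            for x in t.flatten():
                w /= factorial(int(x))
            return w

        keys = sorted(counts)
        weights = np.array([table_weight(k) for k in keys])
        expected = weights / weights.sum() * n_draws
        observed = np.array([counts[k] for k in keys])
        res = stats.chisquare(observed, expected)
        assert res.pvalue > 0.01


class TestZRho:
    def _lengths(self, index):
        return pd.Series(900.0, index=index)

    def test_copied_columns_give_positive_z(self):
        counts = pd.DataFrame(
            {"a": [30, 1, 1, 25, 2], "b": [28, 2, 1, 30, 1]},
            index=[f"g{i}" for i in range(5)],
        )
        res = cv.z_rho(counts, self._lengths(counts.index), n_rand=500, seed=0)
        assert res.z_squared > 0
        assert res.rho_squared > 0.8

    def test_matched_margins_null_centered(self):
        """Independent placements with matched margins give Z_rho centered near 0."""
        rng = np.random.default_rng(11)
        zs = []
        for _ in range(40):
            counts = pd.DataFrame(
                {
                    "a": rng.multinomial(40, np.full(8, 1 / 8)),
                    "b": rng.multinomial(35, np.full(8, 1 / 8)),
                },
                index=[f"g{i}" for i in range(8)],
            )
            res = cv.z_rho(counts, self._lengths(counts.index), n_rand=300,
                           seed=int(rng.integers(2**31)))
            if np.isfinite(res.z_squared):
                zs.append(res.z_squared)
        mean = np.mean(zs)
        se = np.std(zs, ddof=1) / np.sqrt(len(zs))
        assert abs(mean) <= 4 * se

    def test_invariant_to_row_reordering(self):
        counts = pd.DataFrame(
            {"a": [10, 0, 3, 7, 1], "b": [8, 1, 4, 6, 0]},
            index=[f"g{i}" for i in range(5)],
        )
        lengths = pd.Series([600.0, 900, 1200, 800, 1000], index=counts.index)
        r1 = cv.z_rho(counts, lengths, n_rand=400, seed=9)
        order = [3, 1, 4, 0, 2]
        counts2 = counts.iloc[order]
        r2 = cv.z_rho(counts2, lengths, n_rand=400, seed=9)
        assert r1.rho_squared == pytest.approx(r2.rho_squared)
        assert r1.z_squared == pytest.approx(r2.z_squared, abs=0.3)

    def test_zrho_anova_zero_f_for_equal_values(self):
        df = pd.DataFrame(
            {
                "taxon": ["T1"] * 3 + ["T2"] * 3,
                "pair": ["1v10", "1v100", "10v100"] * 2,
                "z_squared": [0.5] * 6,
            }
        )
        res = cv.zrho_anova(df, n_perm=99, seed=0)
        assert res.statistic == 0.0
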