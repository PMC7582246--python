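"""Rank aggregation, Friedman/Dunn statistics and divergence screening."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from gaitstgp import ranking
from gaitstgp.params import STGP_NAMES

COMBOS = ["F", "P", "FP", "S", "FS", "PS", "FPS", "T", "FT", "PT", "FPT", "ST", "FST", "PST", "FPST"]

#: published per-parameter ranks of the 15 sensor combinations (rank 1 =
#: lowest mean NAPE), used as a frozen arithmetic fixture
PUBLISHED_RANKS = pd.DataFrame(
    [
        [8, 14, 3, 11, 4, 15, 9, 1, 2, 5, 7, 13, 6, 10, 12],
        [3, 15, 2, 13, 7, 14, 12, 5, 1, 11, 4, 10, 8, 9, 6],
        [15, 3, 11, 7, 14, 5, 13, 10, 12, 8, 2, 6, 1, 9, 4],
        [14, 3, 15, 4, 6, 2, 11, 10, 7, 5, 12, 8, 1, 13, 9],
        [1, 4, 3, 12, 6, 7, 5, 8, 2, 9, 15, 13, 11, 10, 14],
        [2, 7, 4, 1, 12, 5, 6, 11, 3, 8, 15, 9, 13, 14, 10],
        [7, 14, 11, 4, 3, 1, 6, 13, 2, 15, 12, 5, 10, 9, 8],
        [7, 15, 11, 2, 9, 8, 4, 14, 3, 13, 5, 6, 10, 12, 1],
        [10, 14, 15, 2, 1, 9, 4, 13, 7, 11, 3, 5, 6, 12, 8],
        [11, 13, 14, 1, 3, 4, 6, 15, 8, 12, 9, 7, 2, 10, 5],
        [5, 15, 11, 9, 2, 8, 6, 14, 10, 13, 1, 4, 7, 12, 3],
        [8, 15, 6, 9, 7, 14, 13, 1, 4, 2, 5, 3, 12, 11, 10],
    ],
    index=STGP_NAMES,
    columns=COMBOS,
    dtype=float,
)

PUBLISHED_AVERAGE = [7.6, 11.0, 8.8, 6.3, 6.2, 7.7, 7.9, 9.6, 5.1, 9.3, 7.5, 7.4, 7.3, 10.9, 7.5]
PUBLISHED_AVG_SPATIAL = [10.0, 8.8, 7.8, 8.8, 7.8, 9.0, 11.3, 6.5, 5.5, 7.3, 6.3, 9.3, 4.0, 10.3, 7.8]
PUBLISHED_AVG_TEMPORAL = [6.3, 11.2, 9.7, 3.7, 5.7, 5.7, 5.2, 12.3, 4.2, 11.3, 9.8, 7.5, 8.7, 11.2, 7.7]


class TestRankCombinations:
    def test_published_rank_matrix_averages(self):
        """Category and overall rank averages reproduce the published table
        to its printed 1-decimal precision, for every combination column.
        (The published 'average general' row is internally inconsistent with
        its constituent rows and is not compared.)"""
        out = ranking.rank_combinations(PUBLISHED_RANKS)
        np.testing.assert_allclose(
            out.loc["average"], PUBLISHED_AVERAGE, atol=0.0501
        )
        np.testing.assert_allclose(
            out.loc["average_spatial"], PUBLISHED_AVG_SPATIAL, atol=0.0501
        )
        np.testing.assert_allclose(
            out.loc["average_temporal"], PUBLISHED_AVG_TEMPORAL, atol=0.0501
        )

    def test_tied_row_gets_mean_rank(self):
        table = pd.DataFrame(
            np.ones((1, 15)), index=["stride_length"], columns=COMBOS
        )
        out = ranking.rank_combinations(table)
        np.testing.assert_allclose(out.loc["stride_length"], 8.0)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.normal(10, 2, (12, 15)), index=STGP_NAMES, columns=COMBOS
        )
        base = ranking.rank_combinations(table)
        perm = rng.permutation(COMBOS)
        out = ranking.rank_combinations(table[perm])
        pd.testing.assert_frame_equal(out, base[perm])


def _classic_friedman(x):
    """Independent oracle: textbook tie-free Friedman statistic."""
    n, k = x.shape
    ranks = np.argsort(np.argsort(x, axis=1), axis=1) + 1.0
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)


class TestFriedman:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_statistic(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (6, 4))
        q, _ = ranking.friedman_test(x)
        assert q == pytest.approx(_classic_friedman(x), abs=1e-9)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, (8, 5))
        q, _ = ranking.friedman_test(x)
        q_sp, _ = stats.friedmanchisquare(*[x[:, j] for j in range(5)])
        assert q == pytest.approx(q_sp, abs=1e-9)

    def test_exact_p_small_case(self):
        """4 blocks x 3 treatments: p agrees with exhaustive enumeration of
        the within-block rank permutations."""
        x = np.array([[1.0, 2.0, 5.0], [2.0, 1.0, 4.0], [1.5, 2.5, 3.0], [0.5, 2.0, 2.5]])
        q_obs, p_impl = ranking.friedman_test(x)
        perms = list(itertools.permutations([1.0, 2.0, 3.0]))
        hits = total = 0
        for assignment in itertools.product(perms, repeat=4):
            q = _classic_friedman(np.asarray(assignment))
            total += 1
            if q >= q_obs - 1e-12:
                hits += 1
        assert p_impl == pytest.approx(hits / total, abs=0.01)

    def test_identical_columns_zero_statistic(self):
        x = np.tile(np.arange(4.0)[:, None], (1, 5))
        q, p = ranking.friedman_test(x)
        assert q == 0.0 and p == 1.0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            ranking.friedman_test(np.ones((1, 5)))


class TestDunn:
    def test_bonferroni_budget(self):
        ranks = pd.Series(np.linspace(5, 11, 15), index=COMBOS)
        res = ranking.dunn_posthoc(ranks, n_blocks=100)
        assert res.n_comparisons == 15 * 14 // 2 == 105
        assert round(res.adjusted_alpha, 6) == 0.000476

    def test_equal_ranks_give_p_one(self):
        ranks = pd.Series(np.full(15, 8.0), index=COMBOS)
        res = ranking.dunn_posthoc(ranks, n_blocks=50)
        assert (res.p_adjusted.values == 1.0).all()

    def test_requires_blocks(self):
        with pytest.raises(ValueError):
            ranking.dunn_posthoc(pd.Series([1.0, 2.0]), n_blocks=1)

    def test_larger_separation_smaller_p(self):
        ranks = pd.Series(np.linspace(1, 15, 15), index=COMBOS)
        res = ranking.dunn_posthoc(ranks, n_blocks=500)
        assert res.p_adjusted.loc["F", "FPST"] < res.p_adjusted.loc["F", "P"]


class TestHomogeneousSubsets:
    def test_all_nonsignificant_single_subset(self):
        ranks = pd.Series(np.linspace(7.9, 8.1, 15), index=COMBOS)
        p = pd.DataFrame(np.ones((15, 15)), index=COMBOS, columns=COMBOS)
        subsets = ranking.homogeneous_subsets(ranks, p, alpha=0.05)
        assert len(subsets) == 1 and len(subsets[0]) == 15

    def test_all_significant_singletons(self):
        ranks = pd.Series(np.arange(15.0) + 1, index=COMBOS)
        p = pd.DataFrame(np.zeros((15, 15)), index=COMBOS, columns=COMBOS)
        subsets = ranking.homogeneous_subsets(ranks, p, alpha=0.05)
        assert len(subsets) == 15 and all(len(s) == 1 for s in subsets)

    def test_three_tier_structure(self):
        """Clearly separated rank tiers come out as three subsets."""
        names = COMBOS
        ranks = pd.Series(
            [2.0] * 5 + [8.0] * 5 + [14.0] * 5, index=names
        )
        p = pd.DataFrame(np.ones((15, 15)), index=names, columns=names)
        for a, b in itertools.combinations(names, 2):
            if abs(ranks[a] - ranks[b]) > 3:
                p.loc[a, b] = p.loc[b, a] = 0.0001
        subsets = ranking.homogeneous_subsets(ranks, p, alpha=0.05)
        assert [len(s) for s in subsets] == [5, 5, 5]
        assert set(subsets[0]) == set(names[:5])

    def test_cover_all_treatments(self):
        rng = np.random.default_rng(3)
        ranks = pd.Series(rng.uniform(1, 15, 15), index=COMBOS)
        p = pd.DataFrame(rng.uniform(0, 1, (15, 15)), index=COMBOS, columns=COMBOS)
        p = (p + p.T) / 2
        subsets = ranking.homogeneous_subsets(ranks, p, alpha=0.05)
        assert set().union(*map(set, subsets)) == set(COMBOS)


class TestJSDivergence:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.5, 2, 100)
        assert ranking.js_divergence(a, b) == ranking.js_divergence(b, a)

    def test_identical_samples_zero(self):
        a = np.random.default_rng(0).normal(10, 2, 500)
        assert ranking.js_divergence(a, a) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_supports_log2(self):
        a = np.random.default_rng(1).uniform(0, 1, 500)
        b = a + 100.0
        assert ranking.js_divergence(a, b) == pytest.approx(math.log(2), abs=1e-4)
        assert ranking.js_divergence(a, b, base=2) == pytest.approx(1.0, abs=1e-4)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranking.js_divergence([], [1.0])

    def test_matches_quadrature_oracle(self):
        """Histogram JSD of two large Gaussian samples agrees with direct
        numerical integration of the continuous JSD."""
        mu = 1.0
        p = lambda x: stats.norm.pdf(x, 0, 1)
        q = lambda x: stats.norm.pdf(x, mu, 1)
        m = lambda x: 0.5 * (p(x) + q(x))

        def integrand(x):
            out = 0.0
            for f in (p, q):
                fx = f(x)
                if fx > 1e-300:
                    out += 0.5 * fx * math.log(fx / m(x))
            return out

        oracle, _ = integrate.quad(integrand, -10, 12, limit=200)
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 40_000)
        b = rng.normal(mu, 1, 40_000)
        est = ranking.js_divergence(a, b, bins=30)
        assert est == pytest.approx(oracle, abs=0.02)


class TestOODScreen:
    def _pool(self, rng, n=500):
        return pd.DataFrame(
            {"subject_id": "train"}
            | {k: rng.normal(100, 10, n) for k in STGP_NAMES}
        )

    def test_in_distribution_not_flagged(self):
        rng = np.random.default_rng(0)
        pool = self._pool(rng)
        test = pd.DataFrame(
            {"subject_id": "S99"} | {k: rng.normal(100, 10, 200) for k in STGP_NAMES}
        )
        rep = ranking.ood_screen(test, pool, threshold=0.2)
        assert (rep.jsd < 0.1).all()
        assert (rep.flag == "ok").all()

    def test_shifted_subject_flagged(self):
        rng = np.random.default_rng(1)
        pool = self._pool(rng)
        cols = {k: rng.normal(100, 10, 100) for k in STGP_NAMES}
        cols["stride_length"] = rng.normal(150, 10, 100)  # +5 population SDs
        test = pd.DataFrame({"subject_id": "S21"} | cols)
        rep = ranking.ood_screen(test, pool, threshold=0.2)
        row = rep[(rep.subject_id == "S21") & (rep.parameter == "stride_length")]
        assert (row.flag == "out_of_distribution").all()

    def test_self_screen_near_zero(self):
        rng = np.random.default_rng(2)
        pool = self._pool(rng)
        rep = ranking.ood_screen(
            pool.assign(subject_id="train"), pool, threshold=0.2
        )
        assert (rep.jsd < 0.05).all()

    def test_insufficient_strides_flagged(self):
        rng = np.random.default_rng(3)
        pool = self._pool(rng)
        test = pd.DataFrame(
            {"subject_id": "S01"} | {k: rng.normal(100, 10, 3) for k in STGP_NAMES}
        )
        rep = ranking.ood_screen(test, pool)
        assert (rep.flag == "insufficient_data").all()
        assert rep.jsd.isna().all()
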