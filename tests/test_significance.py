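import numpy as np
import pytest

from topomap import (
    ConfigurationError,
    MEASURE_NAMES,
    SampledMap,
    benjamini_hochberg,
    bonferroni,
    permutation_test,
    pooled_permutation_test,
)
from topomap.measures import POLARITY, compute_measure
from topomap.significance import _Kernel, _multiset_permutations, _n_distinct_permutations

import reference


class TestExactMode:
    def test_perfect_line_pc_p_is_2_of_120(self, perfect_line):
        res = permutation_test(perfect_line, "PC", m=10_000, seed=0)
        assert res.mode == "exact"
        assert res.n_samples == 120
        assert res.n_more_ordered == 2  # identity and full reversal reach PC = 1
        assert res.p == pytest.approx(2 / 120)

    def test_matches_brute_force_enumerator(self, perfect_line):
        from topomap import pearson_distance_correlation

        p_ref, count, total = reference.brute_force_exact_p(
            perfect_line, lambda m: pearson_distance_correlation(m).value,
            more_ordered_is_larger=True,
        )
        res = permutation_test(perfect_line, "PC", m=10_000, seed=0)
        assert total == 120 and count == 2
        assert res.p == pytest.approx(p_ref)

    def test_identical_labels_give_p_one(self, jittered_grid_factory):
        m = jittered_grid_factory(k=3, seed=0).with_labels(np.zeros(9))
        res = permutation_test(m, "ZM", m=999, seed=0)
        assert res.mode == "exact"
        assert res.p == 1.0

    def test_duplicate_labels_reduce_distinct_count(self):
        assert _n_distinct_permutations(np.array([1.0, 1, 2])) == 3
        assert _n_distinct_permutations(np.array([1.0, 2, 3])) == 6
        perms = np.array(list(_multiset_permutations([1.0, 1, 2])))
        assert len(np.unique(perms, axis=0)) == 3

    @pytest.mark.parametrize("name", MEASURE_NAMES)
    def test_exact_agrees_with_monte_carlo_on_small_map(self, name, random_map_factory):
        m = random_map_factory(n=6, seed=2)
        exact = permutation_test(m, name, m=720, seed=1)
        assert exact.mode == "exact" and exact.n_samples == 720
        mc = permutation_test(m, name, m=9_999, seed=7, mode="monte_carlo")
        assert mc.mode == "monte_carlo"
        se = np.sqrt(exact.p * (1 - exact.p) / mc.n_samples)
        assert abs(mc.p - exact.p) < 4 * se + 1e-3


class TestMonteCarlo:
    def test_p_never_zero_and_bounded_below(self, jittered_grid_factory):
        m = jittered_grid_factory(k=4, seed=0, labels="x")
        res = permutation_test(m, "PC", m=99, seed=5)
        assert res.p >= 1 / (99 + 1)

    def test_same_seed_is_bit_identical(self, random_map_factory):
        m = random_map_factory(n=15, seed=4)
        a = permutation_test(m, "SC", m=499, seed=11)
        b = permutation_test(m, "SC", m=499, seed=11)
        assert (a.p, a.n_more_ordered, a.measure.value) == (
            b.p, b.n_more_ordered, b.measure.value
        )

    def test_invalid_m_rejected(self, random_map_factory):
        with pytest.raises(ConfigurationError):
            permutation_test(random_map_factory(), "PC", m=0)

    @pytest.mark.parametrize("name", MEASURE_NAMES)
    @pytest.mark.parametrize("periodic", [False, True])
    def test_kernel_statistic_orders_like_plain_measure(
        self, name, periodic, random_map_factory
    ):
        """The vectorized permutation kernel must rank label arrangements
        exactly as the plain measure does (it may differ by a monotone
        transform)."""
        m = random_map_factory(n=10, seed=3, periodic=periodic)
        kernel = _Kernel(m, name)
        rng = np.random.default_rng(0)
        perms = np.array([rng.permutation(m.n) for _ in range(30)])
        fast = kernel.stat(m.labels[perms])
        kwargs = {"tie_mc": 1, "seed": 0} if name == "TP" else {}
        plain = np.array(
            [compute_measure(m.with_labels(m.labels[p]), name, **kwargs).value for p in perms]
        )
        sign = 1 if POLARITY[name] == "ascending" else -1
        fast, plain = sign * fast, sign * plain
        # pairwise monotonicity with a float tolerance: whenever the plain
        # measure clearly separates two arrangements, the kernel must too
        df = fast[:, None] - fast[None, :]
        dp = plain[:, None] - plain[None, :]
        tol_f = 1e-9 * np.max(np.abs(fast))
        tol_p = 1e-9 * np.max(np.abs(plain))
        assert not np.any((dp > tol_p) & (df < -tol_f))
        assert not np.any((dp < -tol_p) & (df > tol_f))


class TestNullCalibration:
    def test_pc_rejection_rate_matches_alpha(self, random_map_factory):
        rng = np.random.default_rng(42)
        rejections = 0
        runs = 400
        for r in range(runs):
            m = random_map_factory(n=20, seed=1000 + r)
            m = m.with_labels(rng.permutation(m.labels))
            res = permutation_test(m, "PC", m=199, seed=r)
            rejections += res.p <= 0.05
        rate = rejections / runs
        # 95% binomial interval around 0.05 at 400 runs
        assert 0.05 - 2.2 * np.sqrt(0.05 * 0.95 / runs) <= rate <= 0.05 + 2.2 * np.sqrt(
            0.05 * 0.95 / runs
        )


class TestPooled:
    def test_two_perfect_lines_highly_significant(self, perfect_line):
        maps = [perfect_line, perfect_line.with_labels(perfect_line.labels * 2)]
        res = pooled_permutation_test(maps, m=9_999, seed=0)
        assert res.p <= 0.01

    def test_single_subject_reduces_to_pc_test(self, random_map_factory):
        m = random_map_factory(n=12, seed=9)
        pooled = pooled_permutation_test([m], m=999, seed=13)
        single = permutation_test(m, "PC", m=999, seed=13)
        assert pooled.p == single.p
        assert pooled.n_more_ordered == single.n_more_ordered

    def test_null_p_roughly_uniform(self, random_map_factory):
        from scipy.stats import kstest

        pvals = []
        for r in range(200):
            maps = [
                random_map_factory(n=8, seed=3000 + 2 * r),
                random_map_factory(n=10, seed=3001 + 2 * r),
            ]
            pvals.append(pooled_permutation_test(maps, m=199, seed=r).p)
        # discrete p-grid: KS against uniform is conservative but indicative
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCorrections:
    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_bh_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_bh_equal_ps_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_bh_rejects_out_of_range(self):
        from topomap import InvalidInputError

        with pytest.raises(InvalidInputError):
            benjamini_hochberg([0.5, 1.2])

    def test_bonferroni_is_uncapped(self):
        # 7 simultaneous map tests can push a weak p far above 1
        np.testing.assert_allclose(bonferroni([3.9 / 7], k=7), [3.9])

    def test_bonferroni_trivial_cases(self):
        np.testing.assert_allclose(bonferroni([0.0, 0.1], k=3), [0.0, 0.3])
        np.testing.assert_allclose(bonferroni([0.2, 0.7], k=1), [0.2, 0.7])
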