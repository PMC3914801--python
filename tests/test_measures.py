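import numpy as np
import pytest

from topomap import (
    MEASURE_NAMES,
    POLARITY,
    SampledMap,
    UndefinedMeasureError,
    compute_measure,
    pearson_distance_correlation,
    pearson_multi_subject,
    path_length,
    spearman_distance_correlation,
    topographic_product,
    topological_correlation,
    wiring_length,
    zrehen_measure,
)
from topomap.measures import feature_adjacency_edges

import reference


def needs_delaunay(name):
    return name in ("TC", "PL", "ZM")


class TestPerfectLineIdentities:
    def test_pc_and_sc_equal_one(self, perfect_line):
        assert pearson_distance_correlation(perfect_line).value == pytest.approx(1.0, abs=1e-12)
        assert spearman_distance_correlation(perfect_line).value == pytest.approx(1.0, abs=1e-12)

    def test_label_reversal_preserves_pc(self, perfect_line):
        rev = perfect_line.with_labels(perfect_line.labels[::-1])
        assert pearson_distance_correlation(rev).value == pytest.approx(1.0, abs=1e-12)

    def test_topographic_product_zero_despite_distance_ties(self, perfect_line):
        assert topographic_product(perfect_line, tie_mc=100, seed=0).value == 0.0


class TestPearson:
    def test_permuted_labels_match_bruteforce(self, perfect_line):
        m = perfect_line.with_labels(np.array([0.0, 2, 4, 1, 3]))
        assert pearson_distance_correlation(m).value == pytest.approx(
            reference.ref_pc(m), abs=1e-12
        )

    def test_zero_feature_variance_is_error(self, perfect_line):
        m = perfect_line.with_labels(np.zeros(5))
        with pytest.raises(UndefinedMeasureError):
            pearson_distance_correlation(m)


class TestMultiSubject:
    def test_single_subject_reduces_to_pc(self, random_map_factory):
        m = random_map_factory(n=10, seed=3)
        assert pearson_multi_subject([m]).value == pytest.approx(
            pearson_distance_correlation(m).value, abs=1e-12
        )

    def test_two_perfect_lines_give_one(self, perfect_line):
        assert pearson_multi_subject([perfect_line, perfect_line]).value == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_concatenated_pair_list_oracle(self, random_map_factory):
        maps = [random_map_factory(n=9, seed=s) for s in (1, 2)]
        assert pearson_multi_subject(maps).value == pytest.approx(
            reference.ref_pc_multi(maps), abs=1e-12
        )

    def test_mixed_periodicity_rejected(self, random_map_factory):
        from topomap import ConfigurationError

        maps = [random_map_factory(n=8, seed=1), random_map_factory(n=8, seed=2, periodic=True)]
        with pytest.raises(ConfigurationError):
            pearson_multi_subject(maps)


class TestSpearman:
    def test_invariant_when_map_and_labels_warp_together(self, perfect_line):
        """A 1-D map stretched by a strictly increasing transform applied to
        positions and labels alike keeps SC = 1: only orderings matter."""
        warped_axis = perfect_line.positions[:, 0] ** 3
        stretched = SampledMap(
            positions=np.column_stack([warped_axis, np.zeros(5)]),
            labels=warped_axis,
        )
        assert spearman_distance_correlation(stretched).value == pytest.approx(
            1.0, abs=1e-12
        )

    def test_rank_then_correlate_oracle(self, random_map_factory):
        m = random_map_factory(n=10, seed=17)
        import reference

        assert spearman_distance_correlation(m).value == pytest.approx(
            reference.ref_sc(m), abs=1e-12
        )


class TestTopologicalCorrelation:
    def test_triangle_has_degenerate_geodesic_variance(self):
        m = SampledMap(positions=[[0.0, 0], [1, 0], [0, 1]], labels=[0.0, 1, 2])
        with pytest.raises(UndefinedMeasureError):
            topological_correlation(m)

    def test_matches_enumeration_oracle(self, jittered_grid_factory):
        m = jittered_grid_factory(k=3, seed=2, labels="x")
        assert topological_correlation(m).value == pytest.approx(
            reference.ref_tc(m), abs=1e-10
        )

    def test_shuffled_labels_center_on_zero(self, jittered_grid_factory):
        m = jittered_grid_factory(k=5, seed=4, labels="random")
        rng = np.random.default_rng(0)
        values = [
            topological_correlation(m.with_labels(rng.permutation(m.labels))).value
            for _ in range(200)
        ]
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(np.mean(values)) < 3 * se + 1e-3


class TestWiringLength:
    def test_tied_labels_are_mutually_adjacent(self):
        m = SampledMap(positions=[[0.0, 0], [1, 0], [0, 1]], labels=[0.0, 0, 1])
        edges = {tuple(e) for e in feature_adjacency_edges(m)}
        assert edges == {(0, 1), (0, 2), (1, 2)}

    def test_perfect_line_is_permutation_minimum(self, perfect_line):
        import itertools

        values = []
        for perm in itertools.permutations(range(5)):
            m = perfect_line.with_labels(perfect_line.labels[list(perm)])
            values.append(reference.ref_wl(m))
        observed = wiring_length(perfect_line).value
        assert observed == pytest.approx(min(values), abs=1e-12)
        assert observed == pytest.approx(reference.ref_wl(perfect_line), abs=1e-12)

    def test_scaling_invariance(self, random_map_factory):
        m = random_map_factory(n=10, seed=5)
        scaled = SampledMap(positions=m.positions * 10, labels=m.labels)
        assert wiring_length(scaled).value == pytest.approx(
            wiring_length(m).value, abs=1e-12
        )


class TestPathLength:
    def test_ordered_grid_below_shuffled_mean(self, jittered_grid_factory):
        m = jittered_grid_factory(k=4, seed=1, labels="x")
        observed = path_length(m).value
        rng = np.random.default_rng(1)
        shuffled = [
            path_length(m.with_labels(rng.permutation(m.labels))).value
            for _ in range(500)
        ]
        assert observed < np.mean(shuffled)

    def test_identical_labels_give_zero(self, jittered_grid_factory):
        m = jittered_grid_factory(k=3, seed=0, labels="x")
        flat = m.with_labels(np.zeros(m.n))
        assert path_length(flat).value == 0.0

    def test_scaling_invariance(self, jittered_grid_factory):
        m = jittered_grid_factory(k=4, seed=2, labels="x")
        scaled = SampledMap(positions=m.positions * 7.5, labels=m.labels)
        assert path_length(scaled).value == pytest.approx(path_length(m).value, abs=1e-12)


class TestZrehen:
    def test_triangle_hand_count(self):
        m = SampledMap(positions=[[0.0, 0], [1, 0], [0.5, 0.9]], labels=[0.0, 1, 2])
        res = zrehen_measure(m)
        # only the (label 0, label 2) edge has an intruder: label 1
        assert res.extras["raw_intruder_count"] == 1
        assert res.value == pytest.approx(1 / 3)

    def test_ordered_grid_has_zero_intruders(self):
        # exact regular grid: all Delaunay edges join same or adjacent
        # columns, so column labels leave nothing to interpose
        xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
        m = SampledMap(
            positions=np.column_stack([xs.ravel(), ys.ravel()]), labels=xs.ravel()
        )
        from topomap import delaunay_neighbors

        g = delaunay_neighbors(m.positions)
        assert max(abs(m.labels[i] - m.labels[j]) for i, j in g.edges) == 1.0
        res = zrehen_measure(m)
        assert res.extras["raw_intruder_count"] == 0
        assert res.value == 0.0

    def test_equal_labels_no_intruders(self, jittered_grid_factory):
        m = jittered_grid_factory(k=3, seed=1, labels="x")
        flat = m.with_labels(np.full(m.n, 2.5))
        assert zrehen_measure(flat).extras["raw_intruder_count"] == 0


class TestTopographicProduct:
    def test_scrambled_labels_match_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        m = SampledMap(positions=rng.uniform(size=(4, 2)), labels=rng.normal(size=4))
        assert topographic_product(m).value == pytest.approx(reference.ref_tp(m), abs=1e-12)

    def test_tie_break_mc_is_seeded_and_stable(self):
        # duplicate positions force equidistant-neighbor ties
        pos = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1], [0.5, 0.5]])
        m = SampledMap(positions=pos, labels=np.array([0.0, 1, 2, 3, 4]))
        a = topographic_product(m, tie_mc=200, seed=5)
        b = topographic_product(m, tie_mc=200, seed=5)
        c = topographic_product(m, tie_mc=200, seed=6)
        assert a.value == b.value
        se = a.extras["tie_mc_std"] / np.sqrt(200)
        assert abs(a.value - c.value) < 3 * (se + c.extras["tie_mc_std"] / np.sqrt(200)) + 1e-12


@pytest.mark.parametrize("periodic", [False, True])
@pytest.mark.parametrize("name", MEASURE_NAMES)
def test_oracle_equivalence_random_maps(name, periodic, random_map_factory):
    """Every measure equals its naive loop-based reference on random maps."""
    for seed in range(12):
        m = random_map_factory(n=8 + (seed % 5) * 3, seed=seed, periodic=periodic)
        value = compute_measure(m, name).value
        assert value == pytest.approx(reference.REFERENCES[name](m), abs=1e-10), (
            f"{name} seed={seed}"
        )


@pytest.mark.parametrize("name", MEASURE_NAMES)
def test_invariance_under_rigid_motion_scaling_and_label_shift(name, random_map_factory):
    m = random_map_factory(n=14, seed=21)
    theta = 1.1
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = SampledMap(
        positions=(m.positions @ rot.T) * 3.0 + [5.0, -1.0], labels=m.labels + 10.0
    )
    v1 = compute_measure(m, name).value
    v2 = compute_measure(moved, name).value
    assert v2 == pytest.approx(v1, abs=1e-9)


@pytest.mark.parametrize("name", ["PC", "SC", "TC"])
def test_correlation_measures_center_on_zero_under_shuffling(name, random_map_factory):
    m = random_map_factory(n=25, seed=8)
    rng = np.random.default_rng(3)
    values = [
        compute_measure(m.with_labels(rng.permutation(m.labels)), name).value
        for _ in range(200)
    ]
    se = np.std(values, ddof=1) / np.sqrt(len(values))
    assert abs(np.mean(values)) < 3 * se + 1e-3


def test_polarity_registry_complete():
    assert set(POLARITY) == set(MEASURE_NAMES)
    assert POLARITY["PC"] == POLARITY["SC"] == POLARITY["TC"] == "ascending"
    for name in ("WL", "PL", "ZM", "TP"):
        assert POLARITY[name] == "descending"
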