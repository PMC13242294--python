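import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (
    adjusted_rand_score,
    completeness_score,
    homogeneity_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from stclust.preprocess import build_knn_graph
from stclust.quality_metrics import (
    ari,
    asw,
    chaos,
    contingency,
    homogeneity_completeness,
    nmi,
    pas,
    spatial_autocorrelation,
)

labelings = st.lists(st.integers(0, 2), min_size=2, max_size=12)


def brute_force_ari(a, b):
    """Pair-counting oracle evaluated directly over all sample pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        ss += same_a and same_b
        sd += same_a and not same_b
        ds += not same_a and same_b
        dd += not (same_a or same_b)
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds))
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)


class TestContingency:
    def test_all_cells_one(self):
        table = contingency([0, 0, 1, 1], [0, 1, 0, 1])
        np.testing.assert_array_equal(table.counts, [[1, 1], [1, 1]])

    def test_identical_diagonal(self):
        table = contingency([0, 1, 1, 2], [0, 1, 1, 2])
        assert np.count_nonzero(table.counts - np.diag(np.diag(table.counts))) == 0

    def test_total(self, rng):
        a = rng.integers(0, 3, size=17)
        b = rng.integers(0, 4, size=17)
        assert contingency(a, b).total == 17

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            contingency([0, 1], [0])


class TestAri:
    def test_identity_is_one(self):
        assert ari([0, 0, 1, 1, 2, 2, 2, 1], [0, 0, 1, 1, 2, 2, 2, 1]) == 1.0

    def test_permutation_invariance(self):
        assert ari([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_hand_value_crossed(self):
        assert ari([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_exhaustive_small_oracle(self):
        # every pair of 3-label labelings of 4 spots against the pair-counting oracle
        for a in itertools.product(range(3), repeat=4):
            for b in itertools.product(range(2), repeat=4):
                assert ari(a, b) == pytest.approx(brute_force_ari(a, b), abs=1e-12)

    def test_random_n8_oracle(self, rng):
        for _ in range(50):
            a = rng.integers(0, 4, size=8)
            b = rng.integers(0, 3, size=8)
            assert ari(a, b) == pytest.approx(brute_force_ari(a, b), abs=1e-12)

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            a = rng.integers(0, 5, size=40)
            b = rng.integers(0, 4, size=40)
            assert ari(a, b) == pytest.approx(adjusted_rand_score(a, b), abs=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ari([0], [0])

    @settings(max_examples=40, deadline=None)
    @given(labelings, st.permutations(list(range(3))))
    def test_relabeling_invariance(self, a, perm):
        b = [perm[x] for x in a]
        assert ari(a, b) == pytest.approx(1.0)
        assert nmi(a, b) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(labelings, labelings)
    def test_symmetry(self, a, b):
        if len(a) != len(b):
            b = (b * len(a))[: len(a)]
        assert ari(a, b) == pytest.approx(ari(b, a), abs=1e-12)
        assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-12)


class TestNmi:
    def test_identity_is_one(self):
        assert nmi([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_independent_balanced_zero(self):
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # joint entropies computed independently below
        a = [0, 0, 1, 1]
        b = [0, 0, 0, 1]
        hu = -(0.5 * np.log(0.5)) * 2
        hv = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        mi = 0.5 * np.log(0.5 / (0.5 * 0.75)) + 0.25 * np.log(0.25 / (0.5 * 0.75)) + 0.25 * np.log(
            0.25 / (0.5 * 0.25)
        )
        assert nmi(a, b) == pytest.approx(2 * mi / (hu + hv), abs=1e-12)
        assert nmi(a, b) == pytest.approx(0.344, abs=1e-3)

    def test_single_cluster_pair(self):
        assert nmi([0, 0, 0], [1, 1, 1]) == 1.0

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, size=30)
            b = rng.integers(0, 3, size=30)
            assert nmi(a, b) == pytest.approx(normalized_mutual_info_score(a, b), abs=1e-10)


class TestHomogeneityCompleteness:
    def test_identical(self):
        assert homogeneity_completeness([0, 1, 1], [0, 1, 1]) == (1.0, 1.0)

    def test_refinement_direction(self):
        truth = [0, 0, 0, 0, 1, 1, 1, 1]
        pred = [0, 0, 1, 1, 2, 2, 3, 3]  # splits each true cluster
        hom, comp = homogeneity_completeness(truth, pred)
        assert hom == pytest.approx(1.0)
        assert comp < 1.0

    def test_coarsening_direction(self):
        truth = [0, 0, 1, 1, 2, 2]
        pred = [0, 0, 0, 0, 1, 1]  # merges two true clusters
        hom, comp = homogeneity_completeness(truth, pred)
        assert comp == pytest.approx(1.0)
        assert hom < 1.0

    def test_matches_sklearn(self, rng):
        for _ in range(10):
            truth = rng.integers(0, 3, size=25)
            pred = rng.integers(0, 4, size=25)
            hom, comp = homogeneity_completeness(truth, pred)
            assert hom == pytest.approx(homogeneity_score(truth, pred), abs=1e-10)
            assert comp == pytest.approx(completeness_score(truth, pred), abs=1e-10)


class TestAsw:
    def test_separated_blobs_near_one(self, rng):
        X = np.vstack([rng.normal(size=(30, 2)) * 0.01, rng.normal(size=(30, 2)) * 0.01 + 1000])
        labels = np.repeat([0, 1], 30)
        assert asw(X, labels) > 0.999

    def test_hand_four_points(self):
        X = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
        labels = [0, 0, 1, 1]
        # a = 1 for every point; b = mean distance to the other pair
        b = np.mean([10.0, np.sqrt(101.0)])
        expected = (b - 1) / b
        assert asw(X, labels) == pytest.approx(expected, abs=1e-12)
        assert asw(X, labels) == pytest.approx(silhouette_score(X, labels), abs=1e-12)

    def test_shuffling_decreases(self, rng):
        X = np.vstack([rng.normal(size=(40, 2)), rng.normal(size=(40, 2)) + 8])
        labels = np.repeat([0, 1], 40)
        shuffled = labels.copy()
        rng.shuffle(shuffled)
        assert asw(X, shuffled) < asw(X, labels)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            asw(rng.normal(size=(10, 2)), np.zeros(10))


class TestPas:
    def test_uniform_zero(self):
        coords = np.column_stack([np.arange(20, dtype=float), np.zeros(20)])
        assert pas(np.zeros(20), coords) == 0.0

    def test_contiguous_split_low(self):
        coords = np.array([(i, j) for i in range(10) for j in range(10)], dtype=float)
        labels = (coords[:, 0] >= 5).astype(int)
        assert pas(labels, coords) < 0.25

    def test_alternating_line_interior_abnormal(self):
        n = 40
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        labels = np.arange(n) % 2
        # interior spots see 6 of their 10 nearest neighbors with the other parity
        assert pas(labels, coords) >= (n - 12) / n

    def test_too_few_spots(self):
        coords = np.column_stack([np.arange(5, dtype=float), np.zeros(5)])
        with pytest.raises(ValueError):
            pas(np.zeros(5), coords)


class TestChaos:
    def test_random_split_not_smoother(self, rng):
        coords = rng.normal(size=(60, 2))
        single = np.zeros(60, dtype=int)
        split = rng.integers(0, 2, size=60)
        # a random bipartition stretches within-cluster 1-NN edges
        assert chaos(split, coords) >= chaos(np.r_[single[:-1], 1], coords) - 1e-12

    def test_duplicated_points_zero(self):
        coords = np.repeat(np.random.default_rng(0).normal(size=(10, 2)), 2, axis=0)
        labels = np.zeros(20, dtype=int)
        assert chaos(labels, coords) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        coords = rng.normal(size=(50, 2))
        labels = rng.integers(0, 3, size=50)
        assert chaos(labels, coords) == pytest.approx(chaos(labels, coords * 10), abs=1e-10)

    def test_all_singletons_rejected(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError):
            chaos(np.arange(3), coords)


def _oracle_moran_geary(labels, graph):
    """Independent explicit-loop evaluation of the same statistics."""
    labels = np.asarray(labels)
    n = len(labels)
    k = graph.k
    morans, gearys, sizes = [], [], []
    for lab in np.unique(labels):
        x = (labels == lab).astype(float)
        xbar = x.mean()
        num_m = num_g = 0.0
        for i in range(n):
            for j in graph.neighbor_indices[i]:
                num_m += (1.0 / k) * (x[i] - xbar) * (x[j] - xbar)
                num_g += (1.0 / k) * (x[i] - x[j]) ** 2
        denom = np.sum((x - xbar) ** 2)
        s0 = n
        morans.append((n / s0) * num_m / denom)
        gearys.append(((n - 1) / (2 * s0)) * num_g / denom)
        sizes.append(x.sum())
    return np.average(morans, weights=sizes), np.average(gearys, weights=sizes)


class TestSpatialAutocorrelation:
    def test_two_blocks_on_line(self):
        coords = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        graph = build_knn_graph(coords, k=1)
        labels = np.array([0, 0, 0, 1, 1, 1])
        moran, geary = spatial_autocorrelation(labels, graph)
        o_moran, o_geary = _oracle_moran_geary(labels, graph)
        assert moran == pytest.approx(o_moran, abs=1e-12)
        assert geary == pytest.approx(o_geary, abs=1e-12)
        assert moran > 0.5
        assert geary < 0.5

    def test_alternating_line_is_minus_one(self):
        coords = np.column_stack([np.arange(8, dtype=float), np.zeros(8)])
        graph = build_knn_graph(coords, k=1)
        labels = np.arange(8) % 2
        moran, _ = spatial_autocorrelation(labels, graph)
        assert moran == pytest.approx(-1.0, abs=1e-12)

    def test_coin_flip_near_zero(self, rng):
        coords = np.array([(i, j) for i in range(20) for j in range(20)], dtype=float)
        graph = build_knn_graph(coords, k=4)
        labels = rng.integers(0, 2, size=400)
        moran, geary = spatial_autocorrelation(labels, graph)
        assert abs(moran) < 0.15
        assert abs(geary - 1.0) < 0.2

    def test_oracle_equivalence_random(self, rng):
        coords = rng.normal(size=(30, 2))
        graph = build_knn_graph(coords, k=3)
        labels = rng.integers(0, 3, size=30)
        got = spatial_autocorrelation(labels, graph)
        expected = _oracle_moran_geary(labels, graph)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_labels_rejected(self, rng):
        coords = rng.normal(size=(10, 2))
        graph = build_knn_graph(coords, k=2)
        with pytest.raises(ValueError):
            spatial_autocorrelation(np.zeros(10), graph)


class TestRefinementSmoothness:
    def test_refinement_never_increases_pas(self, sim_small):
        from stclust.domain_clustering import refine_labels

        truth = np.asarray(sim_small.truth_labels)
        rng = np.random.default_rng(0)
        noisy = truth.copy()
        flip = rng.choice(len(noisy), size=len(noisy) // 10, replace=False)
        noisy[flip] = rng.integers(0, truth.max() + 1, size=flip.size)
        graph = build_knn_graph(sim_small.coords, k=6)
        refined = refine_labels(noisy, graph)
        assert pas(refined, sim_small.coords) <= pas(noisy, sim_small.coords)
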