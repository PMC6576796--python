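"""Entropy / mutual-information measures and the coupling network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from fragnet import (community_graph, coupling_matrix, detect_communities,
                     eigenvector_centrality, entropy, finite_size_error,
                     mutual_information, normalized_mi, threshold_and_filter)
from fragnet.info import CouplingMatrix, CouplingNetwork, UNASSIGNED
from fragnet.synth import markov_letters


def make_cm(nmi, dist=None, fmap=None):
    n = nmi.shape[0]
    z = np.zeros_like(nmi)
    if dist is None:
        dist = np.full((n, n), 20.0)
        np.fill_diagonal(dist, 0.0)
    return CouplingMatrix(
        nmi=nmi, raw_mi=z, joint_entropy=z, finite_size_error=z,
        mean_centroid_distance=dist, n_samples=100, replica_count=1,
        fragment_map=fmap or [("A", i + 1) for i in range(n)],
    )


class TestEntropyAndMI:
    @pytest.mark.parametrize("seq,expected", [
        (["A"] * 10, 0.0),
        (["A", "B"] * 8, 1.0),
        (["A", "B", "C", "D"] * 4, 2.0),
    ])
    def test_entropy_closed_forms(self, seq, expected):
        assert entropy(seq) == pytest.approx(expected)

    def test_self_information_equals_entropy(self):
        x = ["A", "B"] * 10
        assert mutual_information(x, x) == pytest.approx(entropy(x))

    def test_independent_constant_gives_zero(self):
        x = ["A", "B"] * 10
        y = ["C"] * 20
        assert mutual_information(x, y) == pytest.approx(0.0)

    def test_hand_enumerated_joint_table(self):
        # joint counts: (A,C)=1 (A,D)=1 (B,C)=1 (B,D)=1 -> H(X,Y)=2, I=0
        x, y = ["A", "A", "B", "B"], ["C", "D", "C", "D"]
        assert entropy(x, y) == pytest.approx(2.0)
        assert mutual_information(x, y) == pytest.approx(1 + 1 - 2)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mutual_information(["A"], ["A", "B"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 4), min_size=1, max_size=60),
           st.lists(st.integers(0, 4), min_size=1, max_size=60))
    def test_mi_bounds_property(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = xs[:n], ys[:n]
        i = mutual_information(x, y)
        assert i >= -1e-9
        assert i <= min(entropy(x), entropy(y)) + 1e-9


class TestNormalizedMI:
    def test_both_constant_defined_as_zero(self):
        assert normalized_mi(["A"] * 5, ["B"] * 5) == 0.0

    def test_perfect_coupling_large_n_approaches_one(self, rng):
        x = rng.integers(0, 2, size=10_000)
        assert normalized_mi(x, x) == pytest.approx(1.0, abs=0.01)

    def test_null_mean_small_after_correction(self, rng):
        # independent uniform 25-letter columns, n=1000, 100 random pairs
        vals = [normalized_mi(rng.integers(0, 25, 1000), rng.integers(0, 25, 1000))
                for _ in range(100)]
        assert np.mean(vals) <= 0.02

    def test_bias_estimate_positive_for_rich_alphabets(self, rng):
        x = rng.integers(0, 25, 200)
        y = rng.integers(0, 25, 200)
        assert finite_size_error(x, y) > 0

    def test_relabeling_invariance(self, rng):
        x = rng.integers(0, 5, 300)
        y = rng.integers(0, 5, 300)
        perm = rng.permutation(5)
        assert normalized_mi(perm[x], y) == pytest.approx(normalized_mi(x, y))


class TestCouplingMatrix:
    def test_single_replica_matches_pairwise_function(self, alphabet, rng):
        m = markov_letters(3, 80, alphabet, switch_rate=0.3, seed=2)
        cm = coupling_matrix(m)
        for i in range(3):
            for j in range(i + 1, 3):
                assert cm.nmi[i, j] == pytest.approx(
                    normalized_mi(m.codes[:, i], m.codes[:, j]), abs=1e-12)

    def test_identical_replicas_average_to_single(self, alphabet):
        m = markov_letters(4, 60, alphabet, seed=3)
        one = coupling_matrix(m)
        two = coupling_matrix([m, m])
        np.testing.assert_allclose(two.nmi, one.nmi)
        assert two.replica_count == 2

    def test_mismatched_fragment_maps_raise(self, alphabet):
        a = markov_letters(3, 20, alphabet, seed=1)
        b = markov_letters(4, 20, alphabet, seed=1)
        with pytest.raises(ValueError, match="fragment maps"):
            coupling_matrix([a, b])

    def test_planted_pair_ranks_top(self, alphabet):
        m = markov_letters(100, 600, alphabet, planted_pairs=((10, 60),),
                           coupling_strength=0.9, seed=42)
        cm = coupling_matrix(m)
        iu = np.triu_indices(100, 1)
        vals = cm.nmi[iu]
        top = np.argmax(vals)
        assert {int(iu[0][top]), int(iu[1][top])} == {10, 60}

    def test_planted_recovery_auc_is_one(self, alphabet):
        """All planted pairs rank above all null pairs at strength >= 0.8
        with >= 500 frames (AUC = 1)."""
        planted = ((5, 40), (12, 70), (25, 55))
        m = markov_letters(80, 500, alphabet, planted_pairs=planted,
                           coupling_strength=0.8, seed=7)
        cm = coupling_matrix(m)
        iu = np.triu_indices(80, 1)
        planted_set = {frozenset(p) for p in planted}
        is_planted = np.array([frozenset((i, j)) in planted_set
                               for i, j in zip(*iu)])
        vals = cm.nmi[iu]
        assert vals[is_planted].min() > vals[~is_planted].max()

    def test_symmetry_and_range(self, alphabet):
        m = markov_letters(10, 100, alphabet, seed=11)
        cm = coupling_matrix(m)
        np.testing.assert_allclose(cm.nmi, cm.nmi.T)
        assert cm.nmi.min() >= 0.0 and cm.nmi.max() <= 1.0
        assert np.all(np.diag(cm.nmi) == 0)


class TestThresholdAndFilter:
    def test_sigma_rule_keeps_only_outlier(self):
        nmi = np.full((6, 6), 0.05)
        np.fill_diagonal(nmi, 0.0)
        nmi[1, 4] = nmi[4, 1] = 0.5
        net = threshold_and_filter(make_cm(nmi), sigma_k=2.0)
        assert [(e[0], e[1]) for e in net.edges] == [(1, 4)]

    def test_explicit_threshold(self):
        nmi = np.array([
            [0, .02, .10, .09],
            [.02, 0, .05, .30],
            [.10, .05, 0, .01],
            [.09, .30, .01, 0.],
        ])
        net = threshold_and_filter(make_cm(nmi), explicit_threshold=0.09)
        kept = {(e[0], e[1]) for e in net.edges}
        assert kept == {(0, 2), (1, 3), (0, 3)}
        assert net.threshold_value == 0.09

    def test_distance_filter_removes_adjacent_pair(self):
        nmi = np.full((4, 4), 0.01)
        np.fill_diagonal(nmi, 0)
        nmi[0, 1] = nmi[1, 0] = 0.6   # adjacent, 5 Å
        nmi[0, 3] = nmi[3, 0] = 0.5   # distant
        dist = np.full((4, 4), 20.0)
        dist[0, 1] = dist[1, 0] = 5.0
        np.fill_diagonal(dist, 0)
        net = threshold_and_filter(make_cm(nmi, dist), sigma_k=1.0,
                                   min_distance=12.0)
        kept = {(e[0], e[1]) for e in net.edges}
        assert (0, 1) not in kept and (0, 3) in kept

    def test_empty_result_is_not_an_error(self):
        nmi = np.zeros((3, 3))
        net = threshold_and_filter(make_cm(nmi), explicit_threshold=0.5)
        assert net.n_edges == 0

    def test_null_calibration_two_sigma(self, alphabet):
        """For independent columns, <= 5% of pairs exceed the 2-sigma rule."""
        m = markov_letters(60, 400, alphabet, switch_rate=0.2, seed=13)
        cm = coupling_matrix(m)
        net = threshold_and_filter(cm, sigma_k=2.0)
        assert net.n_edges / cm.n_candidate_pairs <= 0.05


class TestEigenvectorCentrality:
    def test_complete_graph_uniform(self):
        nmi = np.full((5, 5), 0.3)
        np.fill_diagonal(nmi, 0)
        c = eigenvector_centrality(make_cm(nmi))
        np.testing.assert_allclose(c.centrality, 1.0)

    def test_three_node_path_closed_form(self):
        nmi = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        c = eigenvector_centrality(nmi)
        assert c.eigenvalue == pytest.approx(np.sqrt(2))
        np.testing.assert_allclose(c.centrality,
                                   [1 / np.sqrt(2), 1.0, 1 / np.sqrt(2)],
                                   atol=1e-10)

    def test_matches_power_iteration_oracle(self, rng):
        m = rng.random((20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        c = eigenvector_centrality(m)
        v = np.ones(20)
        for _ in range(10_000):
            v = m @ v
            v /= np.linalg.norm(v)
        lam = v @ m @ v
        np.testing.assert_allclose(c.centrality, v / v.max(), atol=1e-8)
        assert c.eigenvalue == pytest.approx(lam, abs=1e-8)

    def test_scaling_invariance(self, rng):
        m = rng.random((10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        a, b = eigenvector_centrality(m), eigenvector_centrality(7.5 * m)
        np.testing.assert_allclose(a.centrality, b.centrality, atol=1e-10)

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            eigenvector_centrality(np.zeros((4, 4)))


def _network_from_edges(edges, n):
    return CouplingNetwork(
        edges=[(i, j, 1.0, 20.0) for i, j in edges], n_fragments=n,
        fragment_map=[("A", 4 * i + 1) for i in range(n)],
        threshold_value=0.1, threshold_sigma=2.0,
    )


class TestCommunities:
    def test_two_cliques_with_bridge(self):
        cliques = [(i, j) for k in (0, 5) for i in range(k, k + 5)
                   for j in range(i + 1, k + 5)]
        net = _network_from_edges(cliques + [(4, 5)], 10)
        part = detect_communities(net)
        labels = [part.labels[i] for i in range(10)]
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_disconnected_components_respected(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j) for i in range(4, 9) for j in range(i + 1, 9)]
        part = detect_communities(_network_from_edges(edges, 9))
        assert part.labels[0] != part.labels[5]

    def test_small_communities_unassigned(self):
        edges = [(0, 1), (1, 2), (0, 2)]  # size-3 community <= min size
        edges += [(i, j) for i in range(3, 8) for j in range(i + 1, 8)]
        part = detect_communities(_network_from_edges(edges, 8))
        assert part.labels[0] == UNASSIGNED
        assert part.labels[4] != UNASSIGNED

    def test_edgeless_network_all_unassigned(self):
        part = detect_communities(_network_from_edges([], 5))
        assert all(v == UNASSIGNED for v in part.labels.values())

    def test_planted_three_block_recovery(self, rng):
        """Girvan-Newman recovers a planted 3-block partition (ARI >= 0.9)."""
        rng = np.random.default_rng(7)
        n_per, blocks = 8, 3
        truth, edges = [], []
        for b in range(blocks):
            for i in range(b * n_per, (b + 1) * n_per):
                truth.append(b)
        n = blocks * n_per
        for i in range(n):
            for j in range(i + 1, n):
                p = 0.9 if truth[i] == truth[j] else 0.05
                if rng.random() < p:
                    edges.append((i, j))
        part = detect_communities(_network_from_edges(edges, n))
        pred = [part.labels[i] for i in range(n)]
        assert adjusted_rand_score(truth, pred) >= 0.9


class TestCommunityGraph:
    def test_cross_edge_counting(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i + 4, j + 4) for i in range(4) for j in range(i + 1, 4)]
        cross = [(0, 4), (1, 5), (2, 6)]
        net = _network_from_edges(edges + cross, 8)
        part = detect_communities(net)
        cg = community_graph(part, net)
        assert list(cg.edge_weights.values()) == [3]

    def test_no_cross_edges(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i + 4, j + 4) for i in range(4) for j in range(i + 1, 4)]
        net = _network_from_edges(edges, 8)
        cg = community_graph(detect_communities(net), net)
        assert cg.edge_weights == {}
        assert len(cg.node_sizes) == 2

    def test_node_size_is_residue_union(self):
        # fragments at first residues 1 and 2 overlap: residues {1..4}u{2..5}=5
        net = CouplingNetwork(
            edges=[(0, 1, 1.0, 20.0)], n_fragments=2,
            fragment_map=[("A", 1), ("A", 2)],
            threshold_value=0.1, threshold_sigma=2.0,
        )
        part = detect_communities(net, min_reported_size=1)
        assert part.labels[0] == part.labels[1] != UNASSIGNED
        cg = community_graph(part, net)
        assert cg.node_sizes == {part.labels[0]: 5}
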