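import networkx as nx
import numpy as np
import pytest

from mprsnet.network import WeightedNetwork
from mprsnet.propagation import (
    DiffusionModel,
    build_scc_hierarchy,
    compute_similarity_matrix,
    permute_node_weights,
    select_cut_and_score,
)


def scc_partition_oracle(adj: np.ndarray) -> list[frozenset[int]]:
    """Brute-force SCCs by Floyd-Warshall mutual reachability."""
    n = adj.shape[0]
    reach = adj.astype(bool) | np.eye(n, dtype=bool)
    for k in range(n):
        reach |= reach[:, k][:, None] & reach[k, :][None, :]
    mutual = reach & reach.T
    comps, seen = [], set()
    for i in range(n):
        if i not in seen:
            comp = frozenset(np.flatnonzero(mutual[i]).tolist())
            comps.append(comp)
            seen |= set(comp)
    return comps


def labels_to_sets(labels: np.ndarray) -> set[frozenset[int]]:
    return {frozenset(np.flatnonzero(labels == c).tolist()) for c in range(labels.max() + 1)}


class TestSimilarityMatrix:
    def test_two_node_hand_example(self):
        g = nx.Graph([("a", "b")])
        net = WeightedNetwork(graph=g, weights={"a": 1.0, "b": 1.0})
        S = compute_similarity_matrix(net, beta=0.5).S
        assert np.allclose(S, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-12)

    def test_zero_weights_give_zero_matrix(self, path_network):
        net = path_network.with_weights({n: 0.0 for n in path_network.graph.nodes})
        assert np.all(compute_similarity_matrix(net, beta=0.4).S == 0)

    def test_column_sums_equal_node_weights(self, random_network):
        model = compute_similarity_matrix(random_network, beta=0.4)
        w = random_network.weight_vector()
        assert np.abs(model.S.sum(axis=0) - w).max() < 1e-8

    def test_matches_explicit_inverse(self, random_network):
        beta = 0.3
        model = compute_similarity_matrix(random_network, beta=beta)
        A = random_network.adjacency()
        W = A / A.sum(axis=0)[None, :]
        n = W.shape[0]
        S_ref = beta * np.linalg.inv(np.eye(n) - (1 - beta) * W) @ np.diag(random_network.weight_vector())
        assert np.abs(model.S - S_ref).max() < 1e-10

    def test_literal_singular_at_half(self, random_network, path_network):
        for net in (random_network, path_network):
            with pytest.raises(np.linalg.LinAlgError, match="singular|ill-conditioned"):
                compute_similarity_matrix(net, beta=0.5, convention="literal")

    def test_literal_well_conditioned_beta_works(self, path_network):
        model = compute_similarity_matrix(path_network, beta=0.9, convention="literal")
        A = path_network.adjacency()
        W = A / A.sum(axis=0)[None, :]
        M = 0.9 * np.eye(3) - 0.1 * W
        S_ref = np.linalg.inv(M) @ np.diag(path_network.weight_vector())
        assert np.allclose(model.S, S_ref, atol=1e-10)

    def test_invalid_beta_rejected(self, path_network):
        for beta in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError, match="beta"):
                compute_similarity_matrix(path_network, beta=beta)


class TestHierarchy:
    def _model_from_matrix(self, S):
        return DiffusionModel(beta=0.4, convention="hotnet2", S=S,
                              nodes=[f"n{i}" for i in range(S.shape[0])])

    def test_mutual_pair_is_scc(self):
        S = np.full((3, 3), 0.05)
        S[0, 1] = S[1, 0] = 0.9
        h = build_scc_hierarchy(self._model_from_matrix(S))
        top = h.partition(0)  # delta = 0.9
        assert labels_to_sets(top) == {frozenset({0, 1}), frozenset({2})}

    def test_asymmetric_pair_stays_singletons(self):
        S = np.full((3, 3), 0.01)
        S[0, 1] = 0.9  # edge only one way at delta = 0.9
        S[1, 0] = 0.1
        h = build_scc_hierarchy(self._model_from_matrix(S))
        assert labels_to_sets(h.partition(0)) == {frozenset({0}), frozenset({1}), frozenset({2})}

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_equals_brute_force_oracle_at_every_threshold(self, n):
        rng = np.random.default_rng(n)
        for _ in range(35):
            S = rng.random((n, n))
            np.fill_diagonal(S, 0.0)
            h = build_scc_hierarchy(self._model_from_matrix(S))
            offdiag = ~np.eye(n, dtype=bool)
            for t, delta in enumerate(h.thresholds):
                adj = (S >= delta) & offdiag
                assert labels_to_sets(h.partition(t)) == set(scc_partition_oracle(adj))

    def test_partitions_nest_on_20_node_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            S = rng.random((20, 20))
            np.fill_diagonal(S, 0.0)
            h = build_scc_hierarchy(self._model_from_matrix(S))
            prev = h.partition(0)
            for t in range(1, len(h.thresholds)):
                cur = h.partition(t)
                # each earlier (finer) block maps into exactly one later block
                for c in range(prev.max() + 1):
                    members = np.flatnonzero(prev == c)
                    assert len(set(cur[members].tolist())) == 1
                prev = cur

    def test_non_finite_matrix_rejected(self):
        S = np.array([[0.0, np.nan], [1.0, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            build_scc_hierarchy(self._model_from_matrix(S))


class TestPermuteNodeWeights:
    def test_multiset_preserved_and_topology_fixed(self, random_network):
        p = permute_node_weights(random_network, seed=3)
        assert sorted(p.weights.values()) == pytest.approx(sorted(random_network.weights.values()))
        assert set(p.graph.edges) == set(random_network.graph.edges)

    def test_same_seed_same_permutation(self, random_network):
        p1 = permute_node_weights(random_network, seed=5)
        p2 = permute_node_weights(random_network, seed=5)
        assert p1.weights == p2.weights

    def test_single_bin_is_uniform_permutation(self, random_network):
        p = permute_node_weights(random_network, seed=1, n_bins=1)
        moved = sum(p.weights[v] != random_network.weights[v] for v in p.graph.nodes)
        assert moved > 0


class TestSelectCutAndScore:
    def _planted_clique_network(self, seed=0):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        clique = [f"c{i}" for i in range(8)]
        g.add_edges_from((a, b) for i, a in enumerate(clique) for b in clique[i + 1:])
        bg = [f"b{i:02d}" for i in range(40)]
        g.add_edges_from(zip(bg, bg[1:]))
        for _ in range(25):
            g.add_edge(*rng.choice(bg, 2, replace=False))
        g.add_edge(clique[0], bg[0])
        g.remove_edges_from(nx.selfloop_edges(g))
        weights = {n: (5.0 if n in clique else 0.0) for n in g.nodes}
        return WeightedNetwork(graph=g, weights=weights), set(clique)

    def test_planted_clique_recovered_with_min_p(self):
        net, clique = self._planted_clique_network()
        model = compute_similarity_matrix(net, beta=0.4)
        h = build_scc_hierarchy(model)
        _, mods = select_cut_and_score(h, net, beta=0.4, n_perm=99, seed=2)
        assert mods, "planted clique not detected"
        best = max(mods, key=lambda m: len(set(m.genes) & clique))
        assert set(best.genes) == clique
        assert best.perm_p == pytest.approx(1 / 100)

    def test_min_attainable_p_is_one_over_nperm_plus_one(self):
        net, _ = self._planted_clique_network()
        h = build_scc_hierarchy(compute_similarity_matrix(net, beta=0.4))
        _, mods = select_cut_and_score(h, net, beta=0.4, n_perm=24, seed=2)
        assert min(m.perm_p for m in mods) >= 1 / 25

    def test_too_few_permutations_rejected(self, random_network):
        h = build_scc_hierarchy(compute_similarity_matrix(random_network, beta=0.4))
        with pytest.raises(ValueError, match="n_perm"):
            select_cut_and_score(h, random_network, n_perm=10)

    def test_degenerate_thresholds_rejected(self):
        g = nx.Graph([("a", "b")])
        net = WeightedNetwork(graph=g, weights={"a": 1.0, "b": 1.0})
        model = compute_similarity_matrix(net, beta=0.5)
        h = build_scc_hierarchy(model)  # single distinct off-diagonal value
        with pytest.raises(ValueError, match="degenerate"):
            select_cut_and_score(h, net, beta=0.5, n_perm=20)

    def test_deterministic_under_seed(self):
        net, _ = self._planted_clique_network()
        h = build_scc_hierarchy(compute_similarity_matrix(net, beta=0.4))
        out1 = select_cut_and_score(h, net, beta=0.4, n_perm=30, seed=9)
        out2 = select_cut_and_score(h, net, beta=0.4, n_perm=30, seed=9)
        assert out1[0] == out2[0]
        assert [(m.module_id, m.genes, m.perm_p) for m in out1[1]] == \
               [(m.module_id, m.genes, m.perm_p) for m in out2[1]]
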