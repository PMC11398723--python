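"""Louvain modularity, map equation, Infomap-style search, ARI."""

import itertools

import numpy as np
import pytest

import ednet
from ednet.community import (compare_partitions, infomap_partition, louvain,
                             map_equation_codelength, modularity_q)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def all_partitions(n):
    """Every set partition of n items (restricted growth strings)."""
    if n == 1:
        yield [0]
        return
    for p in all_partitions(n - 1):
        for k in range(max(p) + 2):
            yield p + [k]


def brute_force_max_q(w, gamma=1.0):
    best, best_p = -np.inf, None
    for p in all_partitions(w.shape[0]):
        q = modularity_q(w, np.array(p), gamma)
        if q > best:
            best, best_p = q, p
    return best, np.array(best_p)


def codelength_expanded_form(w, labels):
    """Map equation via the expanded plogp identity (independent algebra)."""
    def plogp(x):
        x = np.atleast_1d(np.asarray(x, float))
        return np.where(x > 0, x * np.log2(np.where(x > 0, x, 1.0)), 0.0)

    l_tot = w.sum()
    p = w.sum(axis=1) / l_tot
    labels = np.asarray(labels)
    q_m, p_m = [], []
    for m in np.unique(labels):
        idx = labels == m
        within = w[np.ix_(idx, idx)].sum() / l_tot
        p_m.append(p[idx].sum())
        q_m.append(p[idx].sum() - within)
    q_m, p_m = np.array(q_m), np.array(p_m)
    return float(plogp(q_m.sum()).sum() - 2 * plogp(q_m).sum()
                 - plogp(p).sum() + plogp(q_m + p_m).sum())


def two_cliques(k=3):
    w = np.zeros((2 * k, 2 * k))
    for a, b in itertools.combinations(range(k), 2):
        w[a, b] = w[b, a] = 1.0
    for a, b in itertools.combinations(range(k, 2 * k), 2):
        w[a, b] = w[b, a] = 1.0
    return w


class TestModularityQ:
    def test_single_module_is_zero_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(4, 12)
            a = rng.random((n, n))
            w = (a + a.T) / 2
            np.fill_diagonal(w, 0)
            assert modularity_q(w, np.zeros(n, int), 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques_split_scores_half(self):
        w = two_cliques()
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert modularity_q(w, labels, 1.0) == pytest.approx(0.5)

    def test_clique_split_is_the_enumerated_maximum(self):
        w = two_cliques()
        best, best_p = brute_force_max_q(w)
        assert best == pytest.approx(0.5)
        assert compare_partitions(best_p, np.array([0, 0, 0, 1, 1, 1])) == 1.0

    def test_singleton_partition_is_negative_without_self_loops(self):
        w = two_cliques()
        assert modularity_q(w, np.arange(6), 1.0) < 0

    def test_asymmetric_matrix_rejected(self):
        w = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            modularity_q(w, np.zeros(2, int))

    def test_agrees_with_networkx_including_resolution(self, small_graphs):
        nx = pytest.importorskip("networkx")
        from networkx.algorithms.community import modularity as nx_modularity
        rng = np.random.default_rng(1)
        for name, w in small_graphs.items():
            g = nx.from_numpy_array(w)
            labels = rng.integers(0, 3, w.shape[0])
            comms = [set(np.nonzero(labels == m)[0].tolist())
                     for m in np.unique(labels)]
            for gamma in (1.0, 1.25, 1.5):
                ours = modularity_q(w, labels, gamma)
                theirs = nx_modularity(g, comms, weight="weight",
                                       resolution=gamma)
                assert ours == pytest.approx(theirs, abs=1e-12), name


class TestLouvain:
    def test_attains_enumerated_maximum_on_small_suite(self, small_graphs):
        for name, w in small_graphs.items():
            best, _ = brute_force_max_q(w)
            part = louvain(w, gamma=1.0, seed=3)
            assert part.q == pytest.approx(best, abs=1e-9), name

    def test_recovers_three_planted_cliques(self, planted_cliques):
        w, truth = planted_cliques
        part = louvain(w, gamma=1.0, seed=0)
        assert compare_partitions(part.assignment, truth) == 1.0

    def test_init_at_optimum_is_a_fixed_point(self):
        w = two_cliques()
        init = np.array([1, 1, 1, 2, 2, 2])
        part = louvain(w, gamma=1.0, init_labels=init, seed=0)
        assert np.array_equal(part.assignment, init)

    def test_output_q_never_below_init_q(self, small_graphs):
        rng = np.random.default_rng(2)
        for w in small_graphs.values():
            init = rng.integers(1, 4, w.shape[0])
            part = louvain(w, gamma=1.0, init_labels=init, seed=1)
            assert part.q >= modularity_q(np.where(w > 0, w, 0), init, 1.0) - 1e-12

    def test_deterministic_given_seed(self, planted_cliques):
        w, _ = planted_cliques
        a = louvain(w, gamma=1.25, seed=9)
        b = louvain(w, gamma=1.25, seed=9)
        assert np.array_equal(a.assignment, b.assignment) and a.q == b.q

    def test_module_count_nondecreasing_in_gamma(self, small_graphs,
                                                 planted_cliques):
        graphs = dict(small_graphs)
        graphs["three_cliques"] = planted_cliques[0]
        for name, w in graphs.items():
            if w.sum() == 0:
                continue
            counts = [louvain(w, gamma=g, seed=4).n_modules
                      for g in (1.0, 1.5, 2.0, 2.5)]
            assert np.all(np.diff(counts) >= 0), name

    def test_warm_and_cold_start_reach_equal_q_on_planted_cliques(
            self, planted_cliques):
        w, truth = planted_cliques
        cold = louvain(w, gamma=1.0, seed=0)
        warm = louvain(w, gamma=1.0, init_labels=truth, seed=0)
        assert cold.q == pytest.approx(warm.q, abs=1e-12)

    def test_init_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            louvain(two_cliques(), init_labels=np.array([1, 2]), seed=0)


class TestMapEquation:
    def test_single_module_equals_stationary_entropy(self):
        w = two_cliques()
        w[2, 3] = w[3, 2] = 0.5  # connect so the walk is ergodic
        p = w.sum(axis=1) / w.sum()
        entropy = -np.sum(p * np.log2(p))
        assert map_equation_codelength(w, np.zeros(6, int)) == pytest.approx(entropy)

    def test_two_modules_beat_one_on_disconnected_cliques(self):
        w = two_cliques()
        split = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(RuntimeWarning, match="components"):
            l_split = map_equation_codelength(w, split)
        with pytest.warns(RuntimeWarning, match="components"):
            l_one = map_equation_codelength(w, np.zeros(6, int))
        assert l_split < l_one
        # independent evaluation: perfectly split cliques need log2(3) bits
        assert l_split == pytest.approx(np.log2(3))
        assert l_one == pytest.approx(np.log2(6))

    def test_nested_and_expanded_forms_agree(self, small_graphs):
        rng = np.random.default_rng(3)
        for name, w in small_graphs.items():
            labels = rng.integers(0, 3, w.shape[0])
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ours = map_equation_codelength(w, labels)
            assert ours == pytest.approx(
                codelength_expanded_form(w, labels), abs=1e-10), name

    def test_invariant_to_weight_rescaling(self, planted_cliques):
        w, truth = planted_cliques
        a = map_equation_codelength(w, truth)
        b = map_equation_codelength(2.0 * w, truth)
        assert a == pytest.approx(b, abs=1e-12)

    def test_negative_weights_rejected(self):
        w = -two_cliques()
        with pytest.raises(ValueError, match="nonnegative"):
            map_equation_codelength(w, np.zeros(6, int))


class TestInfomap:
    def test_recovers_three_planted_cliques(self, planted_cliques):
        w, truth = planted_cliques
        part = infomap_partition(w, seed=0)
        assert compare_partitions(part.assignment, truth) == 1.0

    def test_codelength_bounds_degenerate_partitions(self, small_graphs):
        import warnings
        for w in small_graphs.values():
            if w.sum() == 0:
                continue
            part = infomap_partition(w, seed=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                l_one = map_equation_codelength(w, np.zeros(w.shape[0], int))
                l_single = map_equation_codelength(w, np.arange(w.shape[0]))
            assert part.codelength <= l_one + 1e-12
            assert part.codelength <= l_single + 1e-12

    def test_deterministic_given_seed(self, planted_cliques):
        w, _ = planted_cliques
        a = infomap_partition(w, seed=5)
        b = infomap_partition(w, seed=5)
        assert np.array_equal(a.assignment, b.assignment)

    def test_agrees_with_igraph_on_planted_cliques(self, planted_cliques):
        ig = pytest.importorskip("igraph")
        w, _ = planted_cliques
        g = ig.Graph.Weighted_Adjacency(w.tolist(), mode="undirected")
        theirs = g.community_infomap(edge_weights="weight")
        ours = infomap_partition(w, seed=0)
        assert compare_partitions(ours.assignment,
                                  np.array(theirs.membership)) == 1.0


class TestCompare:
    def test_identical_partitions_score_one(self):
        labels = np.array([1, 1, 2, 2, 3])
        assert compare_partitions(labels, labels) == 1.0

    def test_singletons_vs_one_module_scores_zero(self):
        assert compare_partitions(np.arange(6), np.zeros(6, int)) == pytest.approx(0.0)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 3, 20), rng.integers(0, 4, 20)
        assert compare_partitions(a, b) == compare_partitions(b, a)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_partitions(np.zeros(3), np.zeros(4))
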