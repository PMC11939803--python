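import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from maxentnet.network import GeneNetwork
from maxentnet.ranking import (
    ClusterAssignment,
    TripletCountTable,
    cluster_count_entropy,
    cluster_entropy_curve,
    core_set,
    core_subnetwork_and_bridges,
    kmeans_scores,
    triplet_cooccurrence,
    weighted_pagerank,
)
from maxentnet import synthetic


def assign(mapping, k, seed=0):
    return ClusterAssignment(labels=pd.Series(mapping), k=k, seed=seed)


class TestPageRank:
    def test_two_cycle_symmetry(self):
        w = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        for mode in ("row_stochastic", "as_printed"):
            pr = weighted_pagerank(w, ["a", "b"], mode=mode)
            assert np.allclose(pr.scores, [0.5, 0.5])

    def test_star_matches_linear_solve(self, star_weights):
        w, genes = star_weights
        pr = weighted_pagerank(w, genes, mode="row_stochastic")
        m = np.eye(4) - 0.85 * w.T.toarray()
        expected = np.linalg.solve(m, np.full(4, 0.15 / 4))
        expected /= expected.sum()
        assert np.allclose(pr.scores.to_numpy(), expected, atol=1e-6)
        assert pr.scores["C"] == pytest.approx(0.47973, abs=1e-5)
        assert pr.scores["L1"] == pytest.approx(0.17342, abs=1e-5)

    def test_scores_sum_to_one_and_positive(self):
        net = synthetic.random_connected_network(20, seed=1)
        w = net.adjacency.astype(float)
        w = sp.diags(1.0 / np.asarray(w.sum(axis=1)).ravel()) @ w
        for mode in ("row_stochastic", "as_printed"):
            pr = weighted_pagerank(sp.csr_matrix(w), net.gene_ids, mode=mode)
            assert pr.scores.sum() == pytest.approx(1.0, abs=1e-12)
            assert (pr.scores > 0).all()

    def test_doubly_stochastic_fixed_point_is_uniform(self):
        n = 6
        w = sp.csr_matrix(np.full((n, n), 1.0 / n))
        pr = weighted_pagerank(w, [f"g{i}" for i in range(n)])
        assert np.allclose(pr.scores, 1.0 / n, atol=1e-12)

    def test_negative_weight_rejected(self):
        w = sp.csr_matrix(np.array([[0.0, -1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            weighted_pagerank(w, ["a", "b"])


class TestKMeans:
    def test_separated_clumps(self):
        scores = pd.Series(
            [0.10, 0.11, 0.12, 0.50, 0.51, 0.90],
            index=list("abcdef"),
        )
        a = kmeans_scores(scores, k=3, seed=0)
        groups = {}
        for g, c in a.labels.items():
            groups.setdefault(c, set()).add(g)
        assert set(frozenset(v) for v in groups.values()) == {
            frozenset("abc"), frozenset("de"), frozenset("f")
        }

    def test_labels_ascend_with_cluster_mean(self):
        scores = pd.Series([0.10, 0.11, 0.50, 0.51, 0.90, 0.91],
                           index=list("abcdef"))
        a = kmeans_scores(scores, k=3, seed=0)
        assert a.labels["a"] < a.labels["c"] < a.labels["e"]

    def test_k_equals_n(self):
        scores = pd.Series([0.1, 0.2, 0.4, 0.8], index=list("abcd"))
        a = kmeans_scores(scores, k=4, seed=1)
        assert a.labels.nunique() == 4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.uniform(0.01, 1, 50),
                           index=[f"g{i}" for i in range(50)])
        a1 = kmeans_scores(scores, k=5, seed=3)
        a2 = kmeans_scores(scores, k=5, seed=3)
        assert a1.labels.equals(a2.labels)

    def test_k_above_distinct_values_rejected(self):
        scores = pd.Series([0.5, 0.5, 0.5], index=list("abc"))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_scores(scores, k=2, seed=0)


class TestClusterEntropy:
    def test_two_equal_clusters(self):
        a = assign({"a": 1, "b": 1, "c": 2, "d": 2}, k=2)
        assert cluster_count_entropy(a) == pytest.approx(np.log(2))

    def test_single_cluster_is_zero(self):
        a = assign({"a": 1, "b": 1}, k=1)
        assert cluster_count_entropy(a) == 0.0

    def test_one_three_split(self):
        a = assign({"a": 1, "b": 2, "c": 2, "d": 2}, k=2)
        expected = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert cluster_count_entropy(a) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5623, abs=1e-4)

    def test_curve_covers_requested_range(self):
        rng = np.random.default_rng(0)
        scores = {
            s: pd.Series(rng.uniform(0.001, 1, 40),
                         index=[f"g{i}" for i in range(40)])
            for s in ("s1", "s2")
        }
        curve = cluster_entropy_curve(scores, k_min=5, k_max=8)
        assert list(curve.index) == [5, 6, 7, 8]
        assert (curve > 0).all()


class TestTriplets:
    def test_enumeration_example(self):
        a1 = assign({"g1": 1, "g2": 1, "g3": 1, "g4": 2}, k=2)
        a2 = assign({"g1": 1, "g2": 1, "g3": 1, "g4": 1}, k=1)
        table = triplet_cooccurrence({"s1": a1, "s2": a2},
                                     ["g1", "g2", "g3", "g4"])
        assert table.counts[("g1", "g2", "g3")] == 2
        for t in [("g1", "g2", "g4"), ("g1", "g3", "g4"), ("g2", "g3", "g4")]:
            assert table.counts[t] == 1
        assert sorted(table.counts.values()) == [1, 1, 1, 2]

    def test_never_cocluster_gives_empty_table(self):
        a = assign({"g1": 1, "g2": 2, "g3": 3}, k=3)
        table = triplet_cooccurrence({"s1": a}, ["g1", "g2", "g3"])
        assert table.counts == {}

    def test_four_in_one_cluster(self):
        a = assign({g: 1 for g in ["g1", "g2", "g3", "g4"]}, k=1)
        table = triplet_cooccurrence({"s1": a}, ["g1", "g2", "g3", "g4"])
        assert len(table.counts) == 4
        assert all(c == 1 for c in table.counts.values())

    def test_permutation_invariance(self):
        a1 = assign({"g1": 1, "g2": 1, "g3": 1}, k=1)
        a2 = assign({"g1": 1, "g2": 1, "g3": 2}, k=2)
        t_fwd = triplet_cooccurrence({"s1": a1, "s2": a2}, ["g1", "g2", "g3"])
        t_rev = triplet_cooccurrence({"s2": a2, "s1": a1}, ["g3", "g2", "g1"])
        assert t_fwd.counts == t_rev.counts

    def test_combinatorial_guard(self):
        a = assign({f"g{i}": 1 for i in range(250)}, k=1)
        with pytest.raises(ValueError, match="subset"):
            triplet_cooccurrence({"s1": a}, [f"g{i}" for i in range(250)])


class TestCoreSet:
    def _table(self, counts):
        return TripletCountTable(counts=counts, candidates=())

    def test_intersection(self):
        t0 = self._table({("a", "b", "c"): 3, ("b", "c", "d"): 2})
        t1 = self._table({("b", "c", "e"): 4})
        assert core_set(t0, t1, top_n=5) == ("b", "c")

    def test_disjoint_lists_give_empty_core(self):
        t0 = self._table({("a", "b", "c"): 3})
        t1 = self._table({("d", "e", "f"): 3})
        assert core_set(t0, t1, top_n=5) == ()

    def test_tie_at_boundary_resolved_lexicographically(self):
        t0 = self._table({("a", "b", "c"): 5, ("d", "e", "f"): 2, ("g", "h", "i"): 2})
        t1 = self._table({("a", "b", "c"): 5, ("d", "e", "f"): 1})
        # top_n=2 on t0: (a,b,c) then the lexicographically smaller (d,e,f)
        assert core_set(t0, t1, top_n=2) == ("a", "b", "c", "d", "e", "f")

    def test_monotone_in_top_n(self):
        counts0 = {("a", "b", "c"): 5, ("c", "d", "e"): 4, ("f", "g", "h"): 3}
        counts1 = {("a", "b", "c"): 5, ("c", "d", "e"): 1, ("f", "g", "h"): 2}
        prev = set()
        for top_n in (1, 2, 3):
            core = set(core_set(self._table(counts0), self._table(counts1), top_n))
            assert prev <= core
            prev = core

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            core_set(self._table({}), self._table({("a", "b", "c"): 1}), 5)


class TestCoreSubnetwork:
    def test_definition_example(self):
        net = GeneNetwork.from_edges(
            [("c1", "x"), ("x", "c2"), ("c1", "y")],
            gene_ids=["c1", "c2", "x", "y"],
        )
        res = core_subnetwork_and_bridges(net, ["c1", "c2"])
        assert res.bridge_genes == ("x",)
        assert "y" in res.subnetwork.gene_ids
        assert set(res.core_genes) <= set(res.subnetwork.gene_ids)

    def test_adjacent_cores_without_shared_neighbor_have_no_bridge(self):
        net = GeneNetwork.from_edges([("c1", "c2"), ("c2", "z")])
        res = core_subnetwork_and_bridges(net, ["c1", "c2"])
        assert res.bridge_genes == ()

    def test_planted_connector_recovered_as_unique_bridge(self):
        net, core, connector = synthetic.connector_fixture()
        res = core_subnetwork_and_bridges(net, core)
        assert res.bridge_genes == (connector,)

    def test_empty_core_rejected(self):
        net = GeneNetwork.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="empty"):
            core_subnetwork_and_bridges(net, [])
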