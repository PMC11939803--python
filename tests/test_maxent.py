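import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from maxentnet.network import GeneNetwork
from maxentnet.maxent import (
    fit_transition_matrix,
    flow_entropy,
    frozen_nodes,
    markov_chain_entropy,
    oracle_max_entropy,
    stationary_from_expression,
)
from maxentnet import synthetic


def entropy(p):
    p = np.asarray(p, dtype=float)
    return float(-(p * np.log(p)).sum())


def fit_on(net, x, **kw):
    stat, _ = stationary_from_expression(x, gene_ids=net.gene_ids)
    return fit_transition_matrix(net, stat, **kw), stat


class TestStationary:
    def test_l1_normalisation(self):
        stat, mask = stationary_from_expression([2, 3, 5], gene_ids=list("ABC"))
        assert np.allclose(stat.pi, [0.2, 0.3, 0.5])
        assert mask.all()

    def test_drop_zero_renormalises(self):
        stat, mask = stationary_from_expression([0, 1, 3], gene_ids=list("ABC"))
        assert np.allclose(stat.pi, [0.25, 0.75])
        assert stat.gene_ids == ("B", "C")
        assert list(mask) == [False, True, True]

    def test_pseudocount_keeps_all_genes(self):
        stat, mask = stationary_from_expression(
            [0, 1, 3], policy="pseudocount", eps=1.0, gene_ids=list("ABC")
        )
        assert mask.all()
        assert np.allclose(stat.pi, [1 / 7, 2 / 7, 4 / 7])

    def test_all_zero_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            stationary_from_expression([0.0, 0.0, 0.0])

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            stationary_from_expression([1.0, -1.0])


class TestFitClosedForms:
    def test_self_loops_only_gives_identity(self, identity_net):
        res, stat = fit_on(identity_net, [2, 3, 5])
        assert np.allclose(res.transition.matrix.toarray(), np.eye(3))
        assert res.transition.row_residual == 0.0
        assert res.transition.stationarity_residual == 0.0
        assert res.mce == pytest.approx(entropy([0.2, 0.3, 0.5]), abs=1e-12)

    def test_complete_support_rows_equal_pi(self, complete_net4):
        res, stat = fit_on(complete_net4, [1, 2, 3, 4])
        p = res.transition.matrix.toarray()
        assert np.allclose(p, np.tile(stat.pi, (4, 1)), atol=1e-10)
        assert res.mce == pytest.approx(2 * entropy(stat.pi), abs=1e-8)

    def test_complete_uniform_mce_is_2_log_n(self, complete_net4):
        res, _ = fit_on(complete_net4, [1, 1, 1, 1])
        assert res.mce == pytest.approx(2 * np.log(4), abs=1e-8)

    def test_identity_mce_is_entropy_of_pi(self, identity_net):
        res, _ = fit_on(identity_net, [2, 3, 5])
        assert res.mce == pytest.approx(1.029653, abs=1e-6)

    def test_forced_boundary_edge_goes_to_zero(self):
        # column A can only be balanced by A itself, so p_AA = 1 is forced
        net = GeneNetwork.from_edges(
            [("A", "A"), ("A", "B"), ("B", "B")], gene_ids=["A", "B"]
        )
        res, _ = fit_on(net, [0.4, 0.6])
        p = res.transition.matrix.toarray()
        assert p[0, 1] < 1e-4
        assert p[0, 0] == pytest.approx(1.0, abs=1e-8)
        assert res.transition.converged

    def test_requires_self_loops(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "A")])
        stat, _ = stationary_from_expression([1, 1], gene_ids=["A", "B"])
        with pytest.raises(ValueError, match="self-loops"):
            fit_transition_matrix(net, stat)

    def test_gene_mismatch_rejected(self, identity_net):
        stat, _ = stationary_from_expression([1, 1], gene_ids=["X", "Y"])
        with pytest.raises(ValueError, match="align"):
            fit_transition_matrix(identity_net, stat)


class TestOracleEquivalence:
    def test_oracle_refuses_large_graphs(self):
        net = synthetic.random_connected_network(9, seed=0)
        stat, _ = stationary_from_expression(np.ones(9), gene_ids=net.gene_ids)
        with pytest.raises(ValueError, match="refuses"):
            oracle_max_entropy(net, stat)

    def test_oracle_identity_support(self, identity_net):
        stat, _ = stationary_from_expression([2, 3, 5], gene_ids=list("ABC"))
        orc = oracle_max_entropy(identity_net, stat)
        assert np.allclose(orc.matrix.toarray(), np.eye(3), atol=1e-6)

    def test_oracle_complete_support_iid_chain(self):
        net = GeneNetwork(["A", "B"], sp.csr_matrix(np.ones((2, 2))))
        stat, _ = stationary_from_expression([0.3, 0.7], gene_ids=["A", "B"])
        orc = oracle_max_entropy(net, stat)
        assert np.allclose(orc.matrix.toarray(), [[0.3, 0.7], [0.3, 0.7]], atol=1e-6)

    def test_ring_with_loops_matches_fit(self):
        ring = [("g0", "g1"), ("g1", "g2"), ("g2", "g3"), ("g3", "g0")]
        net = GeneNetwork.from_edges(
            ring + [(g, g) for g in ["g0", "g1", "g2", "g3"]]
        )
        res, stat = fit_on(net, [1, 1, 1, 1])
        orc = oracle_max_entropy(net, stat)
        assert abs(res.mce - markov_chain_entropy(orc)) < 1e-5

    @pytest.mark.parametrize("seed", range(8))
    def test_random_graphs_match_and_dominate_feasible_points(self, seed):
        net = synthetic.random_connected_network(5, seed=seed)
        rng = np.random.default_rng(100 + seed)
        res, stat = fit_on(net, rng.uniform(0.2, 1.0, 5))
        orc = oracle_max_entropy(net, stat)
        assert abs(res.mce - markov_chain_entropy(orc)) < 1e-5
        assert abs(res.transition.matrix - orc.matrix).max() < 1e-4
        # no feasible chain (convex mixture with the identity) beats the fit
        for lam in (0.25, 0.5, 0.9):
            mix = res.transition.matrix.toarray() * (1 - lam) + lam * np.eye(5)
            q = stat.pi[:, None] * mix
            h = float(-(q[q > 0] * np.log(q[q > 0])).sum())
            assert h <= res.mce + 1e-6


class TestInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_certificates_and_support_containment(self, seed):
        net = synthetic.generate_network(80, 3, seed=seed).add_self_loops()
        rng = np.random.default_rng(seed)
        res, stat = fit_on(net, rng.lognormal(size=80))
        tm = res.transition
        assert tm.converged
        assert max(tm.row_residual, tm.stationarity_residual) < 1e-8
        # support containment: no probability outside the adjacency
        dense = tm.matrix.toarray()
        assert (dense[net.adjacency.toarray() == 0] == 0).all()

    def test_scale_invariance(self, complete_net4):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res1, _ = fit_on(complete_net4, x)
        res2, _ = fit_on(complete_net4, 37.5 * x)
        assert np.allclose(
            res1.transition.matrix.toarray(), res2.transition.matrix.toarray()
        )
        assert res1.mce == pytest.approx(res2.mce, abs=1e-14)

    def test_bitwise_determinism(self):
        net = synthetic.generate_network(50, 2, seed=3).add_self_loops()
        x = np.random.default_rng(3).lognormal(size=50)
        res1, _ = fit_on(net, x)
        res2, _ = fit_on(net, x)
        assert (res1.transition.matrix != res2.transition.matrix).nnz == 0
        assert res1.mce == res2.mce

    def test_scaling_factors_reproduce_matrix(self):
        net = synthetic.random_connected_network(6, seed=5)
        rng = np.random.default_rng(5)
        res, stat = fit_on(net, rng.uniform(0.5, 1.0, 6))
        tm, sc = res.transition, res.scaling
        rebuilt = sp.diags(sc.alpha) @ tm.support.astype(float) @ sp.diags(sc.beta)
        assert abs(rebuilt - tm.matrix).max() < 1e-10

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_flow_entropy_partitions_mce(self, seed):
        net = synthetic.random_connected_network(6, seed=seed % 100)
        rng = np.random.default_rng(seed)
        res, _ = fit_on(net, rng.uniform(0.1, 1.0, 6))
        out = flow_entropy(res.transition, direction="out")
        inn = flow_entropy(res.transition, direction="in")
        assert out.sum() == pytest.approx(res.mce, abs=1e-10)
        assert inn.sum() == pytest.approx(res.mce, abs=1e-10)
        assert (out >= -1e-15).all()


class TestPresolve:
    def test_dag_with_loops_is_fully_frozen(self):
        net = GeneNetwork.from_edges(
            [("A", "B"), ("B", "C"), ("A", "A"), ("B", "B"), ("C", "C")]
        )
        assert frozen_nodes(net).all()
        res, _ = fit_on(net, [1, 2, 3])
        assert np.allclose(res.transition.matrix.toarray(), np.eye(3))

    def test_trap_set_flow_confined_to_components(self):
        # {C, D} receive no external in-flow, so they may export none
        edges = [
            ("A", "B"), ("B", "A"),
            ("C", "D"), ("D", "C"),
            ("C", "A"), ("D", "B"),
        ]
        net = GeneNetwork.from_edges(
            edges + [(g, g) for g in "ABCD"], gene_ids=list("ABCD")
        )
        res, _ = fit_on(net, [1, 1, 1, 1])
        p = res.transition.matrix.toarray()
        assert p[2, 0] == 0.0 and p[3, 1] == 0.0
        assert res.transition.converged
        assert res.transition.row_residual < 1e-8
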