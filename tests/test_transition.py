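"""Transition-probability matrices and RAS adjustment schemes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rasnet import (
    GPRRule,
    adjust_ras,
    compute_ras,
    parallel_chains,
    path_tp,
    random_dag,
    recursive_tp,
    sample_adjacency,
    scale_reactions,
    transition_matrix,
)
from rasnet.graph import MetabolicGraph
from rasnet.transition import PathExplosionError, TransitionMatrix


def chain_graph(edges):
    """Small helper: graph from (rid, u, v, gene) tuples."""
    g = MetabolicGraph()
    for rid, u, v, gene in edges:
        g.add_reaction(rid, u, v, GPRRule.leaf(gene), {"p"})
    return g


def weighted(graph, weights):
    """Adjacency from an {(u, v): w} mapping, aligned to node order."""
    idx = graph.node_index
    W = np.zeros((len(idx), len(idx)))
    for (u, v), w in weights.items():
        W[idx[u], idx[v]] = w
    return W


def path_tp_oracle(graph, T):
    """Independent enumeration: networkx simple paths to every node."""
    import networkx as nx

    idx = graph.node_index
    acc = np.zeros_like(T.values)
    for target in graph.node_order:
        if target == "N00":
            continue
        for path in nx.all_simple_paths(graph.graph, "N00", target):
            prod = 1.0
            for u, v in zip(path, path[1:]):
                prod *= T.values[idx[u], idx[v]]
            u, v = path[-2], path[-1]
            acc[idx[u], idx[v]] += prod
    return acc


class TestPlainTP:
    def test_row_normalization(self):
        g = chain_graph([("R1", "a", "b", "g1"), ("R2", "a", "c", "g2")])
        W = weighted(g, {("a", "b"): 2.0, ("a", "c"): 6.0})
        T = transition_matrix(W, g.node_order)
        idx = g.node_index
        assert T.values[idx["a"], idx["b"]] == pytest.approx(0.25)
        assert T.values[idx["a"], idx["c"]] == pytest.approx(0.75)

    def test_single_outgoing_edge_gets_probability_one(self):
        g = chain_graph([("R1", "a", "b", "g1")])
        T = transition_matrix(weighted(g, {("a", "b"): 3.7}), g.node_order)
        assert T.values.max() == pytest.approx(1.0)

    def test_zero_out_ras_row_stays_zero(self):
        g = chain_graph([("R1", "a", "b", "g1")])
        T = transition_matrix(weighted(g, {("a", "b"): 0.0}), g.node_order)
        assert (T.values == 0).all()

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(np.array([[0.0, -1.0], [0.0, 0.0]]))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rows_with_positive_mass_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(0, 5, size=(6, 6)) * rng.integers(0, 2, size=(6, 6))
        np.fill_diagonal(W, 0)
        T = transition_matrix(W).values
        sums = T.sum(axis=1)
        positive = W.sum(axis=1) > 0
        np.testing.assert_allclose(sums[positive], 1.0, atol=1e-9)
        assert (sums[~positive] == 0).all()
        assert ((T >= 0) & (T <= 1 + 1e-12)).all()


class TestRecursiveTP:
    def five_node_chain(self):
        #  s -> a (0.7) / s -> z (0.3);  a -> b -> c are sole edges (TP 1)
        g = chain_graph([
            ("R1", "s", "a", "ga"), ("R2", "s", "z", "gz"),
            ("R3", "a", "b", "gb"), ("R4", "b", "c", "gc"),
        ])
        W = weighted(g, {("s", "a"): 7, ("s", "z"): 3,
                         ("a", "b"): 5, ("b", "c"): 2})
        return g, transition_matrix(W, g.node_order)

    def test_branch_probability_propagates_down_the_chain(self):
        g, T = self.five_node_chain()
        Ta = recursive_tp(T, g)
        idx = g.node_index
        assert Ta.values[idx["a"], idx["b"]] == pytest.approx(0.7)
        assert Ta.values[idx["b"], idx["c"]] == pytest.approx(0.7)
        # branch TPs themselves are below 1 and stay untouched
        assert Ta.values[idx["s"], idx["a"]] == pytest.approx(0.7)
        assert Ta.values[idx["s"], idx["z"]] == pytest.approx(0.3)

    def test_root_edge_without_incoming_stays_one(self):
        g = chain_graph([("R1", "a", "b", "g1"), ("R2", "b", "c", "g2")])
        T = transition_matrix(weighted(g, {("a", "b"): 4, ("b", "c"): 2}),
                              g.node_order)
        Ta = recursive_tp(T, g)
        idx = g.node_index
        assert Ta.values[idx["a"], idx["b"]] == 1.0
        assert Ta.values[idx["b"], idx["c"]] == 1.0

    def test_cycle_of_ones_stays_one(self):
        g = chain_graph([("R1", "a", "b", "g1"), ("R2", "b", "c", "g2"),
                         ("R3", "c", "a", "g3")])
        W = weighted(g, {("a", "b"): 1, ("b", "c"): 1, ("c", "a"): 1})
        Ta = recursive_tp(transition_matrix(W, g.node_order), g)
        assert set(np.unique(Ta.values)) == {0.0, 1.0}

    def test_tie_at_one_broken_by_smallest_source_id(self):
        # x -> m and y -> m both have TP 1; recursion from the tie must
        # continue via x (lexicographically smaller), whose upstream branch
        # TP is 0.3, not via y (upstream 0.8)
        g = chain_graph([
            ("R1", "p", "x", "g1"), ("R2", "p", "q", "g2"),
            ("R3", "r", "y", "g3"), ("R4", "r", "w", "g4"),
            ("R5", "x", "m", "g5"), ("R6", "y", "m", "g6"),
            ("R7", "m", "t", "g7"),
        ])
        W = weighted(g, {("p", "x"): 3, ("p", "q"): 7,
                         ("r", "y"): 8, ("r", "w"): 2,
                         ("x", "m"): 5, ("y", "m"): 4, ("m", "t"): 2})
        Ta = recursive_tp(transition_matrix(W, g.node_order), g)
        idx = g.node_index
        assert Ta.values[idx["x"], idx["m"]] == pytest.approx(0.3)
        assert Ta.values[idx["y"], idx["m"]] == pytest.approx(0.8)
        assert Ta.values[idx["m"], idx["t"]] == pytest.approx(0.3)

    def test_entries_below_one_unchanged_and_idempotent(self):
        g, T = self.five_node_chain()
        Ta = recursive_tp(T, g)
        below = T.values < 1
        np.testing.assert_array_equal(Ta.values[below], T.values[below])
        again = recursive_tp(
            TransitionMatrix(Ta.values, "plain", Ta.node_order), g)
        np.testing.assert_array_equal(again.values, Ta.values)

    def test_variant_mismatch_rejected(self):
        g, T = self.five_node_chain()
        Ta = recursive_tp(T, g)
        with pytest.raises(ValueError):
            recursive_tp(Ta, g)


class TestPathTP:
    def test_product_along_chain(self):
        g = chain_graph([
            ("R1", "x", "b", "g1"), ("R2", "x", "q", "g2"),
            ("R3", "b", "c", "g3"), ("R4", "b", "d", "g4"),
        ])
        W = weighted(g, {("x", "b"): 4, ("x", "q"): 6,
                         ("b", "c"): 1, ("b", "d"): 1})
        T = transition_matrix(W, g.node_order)
        Tb = path_tp(T, g, "x")
        idx = g.node_index
        assert Tb.values[idx["b"], idx["c"]] == pytest.approx(0.4 * 0.5)

    def test_unreachable_edge_gets_zero(self):
        g = chain_graph([("R1", "x", "b", "g1"), ("R2", "u", "v", "g2")])
        W = weighted(g, {("x", "b"): 2, ("u", "v"): 5})
        Tb = path_tp(transition_matrix(W, g.node_order), g, "x")
        idx = g.node_index
        assert Tb.values[idx["u"], idx["v"]] == 0.0
        assert Tb.values[idx["x"], idx["b"]] == 1.0

    def test_absent_source_rejected(self):
        g = chain_graph([("R1", "a", "b", "g1")])
        T = transition_matrix(weighted(g, {("a", "b"): 1}), g.node_order)
        with pytest.raises(KeyError):
            path_tp(T, g, "nope")

    def test_path_cap_enforced(self):
        g = random_dag(10, 1.0, seed=0)
        W = np.zeros((10, 10))
        idx = g.node_index
        for e in g.edges():
            W[idx[e.source], idx[e.target]] = 1.0
        T = transition_matrix(W, g.node_order)
        with pytest.raises(PathExplosionError):
            path_tp(T, g, "N00", max_paths=5)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_enumeration_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = random_dag(n, float(rng.uniform(0.2, 0.8)), seed=seed)
        idx = g.node_index
        W = np.zeros((g.n_nodes, g.n_nodes))
        for e in g.edges():
            W[idx[e.source], idx[e.target]] = rng.uniform(0.1, 5.0)
        T = transition_matrix(W, g.node_order)
        Tb = path_tp(T, g, "N00")
        np.testing.assert_allclose(Tb.values, path_tp_oracle(g, T),
                                   rtol=0, atol=1e-12)
        # every individual entry is a probability on a DAG
        assert ((Tb.values >= 0) & (Tb.values <= 1 + 1e-12)).all()

    def test_max_combine_bounded_by_sum(self):
        g = random_dag(8, 0.6, seed=42)
        idx = g.node_index
        rng = np.random.default_rng(42)
        W = np.zeros((8, 8))
        for e in g.edges():
            W[idx[e.source], idx[e.target]] = rng.uniform(0.1, 5.0)
        T = transition_matrix(W, g.node_order)
        assert (path_tp(T, g, "N00", combine="max").values
                <= path_tp(T, g, "N00", combine="sum").values + 1e-12).all()


class TestAdjustRAS:
    @pytest.fixture
    def toy_ras(self, toy_graph, toy_expression):
        return compute_ras(toy_graph, toy_expression)

    @pytest.mark.parametrize("scheme", ["W1", "W2", "W3"])
    def test_identity_on_branchless_chain(self, scheme):
        g = parallel_chains(n_chains=1, chain_length=3)
        genes = sorted(g.gene_universe)
        expr = pd.DataFrame(
            np.random.default_rng(0).uniform(1, 4, size=(len(genes), 3)),
            index=genes, columns=["s1", "s2", "s3"])
        ras = compute_ras(g, expr)
        adj = adjust_ras(ras, g, scheme, x="s")
        pd.testing.assert_frame_equal(adj.values, ras)

    def test_plain_tp_scales_ras(self):
        g = chain_graph([("R1", "a", "b", "g1"), ("R2", "a", "c", "g2")])
        ras = pd.DataFrame({"s": [4.0, 12.0]}, index=["R1", "R2"])
        adj = adjust_ras(ras, g, "W1")
        assert adj.values.loc["R1", "s"] == pytest.approx(1.0)  # 4 * 0.25
        assert adj.values.loc["R2", "s"] == pytest.approx(9.0)

    @pytest.mark.parametrize("scheme", ["W1", "W2"])
    def test_never_exceeds_unadjusted(self, toy_graph, toy_ras, scheme):
        adj = adjust_ras(toy_ras, toy_graph, scheme)
        assert (adj.values.to_numpy() <= toy_ras.to_numpy() + 1e-12).all()
        assert (adj.values.to_numpy() >= 0).all()

    @pytest.mark.parametrize("scheme", ["W2", "W3"])
    def test_adjustment_separates_parallel_chains(self, toy_graph,
                                                  toy_expression, toy_ras,
                                                  scheme):
        """Corresponding chain edges share unadjusted RAS but split after
        adjustment whenever the branch reactions differ."""
        adj = adjust_ras(toy_ras, toy_graph, scheme, x="s").values
        for s in toy_expression.columns:
            branch_differs = toy_ras.loc["R01", s] != toy_ras.loc["R02", s]
            assert branch_differs  # fixture guarantees distinct branch genes
            for a, b in [("R03", "R04"), ("R05", "R06"), ("R07", "R08")]:
                assert toy_ras.loc[a, s] == toy_ras.loc[b, s]
                assert adj.loc[a, s] != adj.loc[b, s]

    def test_mismatched_reactions_rejected(self, toy_graph):
        ras = pd.DataFrame({"s": [1.0]}, index=["bogus"])
        with pytest.raises(ValueError):
            adjust_ras(ras, toy_graph, "W1")

    def test_w3_requires_source_node(self, toy_graph, toy_ras):
        with pytest.raises(ValueError, match="x"):
            adjust_ras(toy_ras, toy_graph, "W3")


class TestScaleReactions:
    def test_rows_standardized(self):
        M = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 1.0, 3.0]],
                         index=["R1", "R2"], columns=list("abc"))
        scaled = scale_reactions(M)
        np.testing.assert_allclose(scaled.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(scaled.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_all_zero_rows_removed(self):
        M = pd.DataFrame([[0.0, 0.0, 0.0], [1.0, 2.0, 4.0]],
                         index=["dead", "live"], columns=list("abc"))
        assert list(scale_reactions(M).index) == ["live"]

    def test_constant_rows_dropped_with_warning(self):
        M = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 4.0]],
                         index=["flat", "live"], columns=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            scaled = scale_reactions(M)
        assert list(scaled.index) == ["live"]

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            scale_reactions(pd.DataFrame({"only": [1.0, 2.0]}))
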