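"""Module mining: hub-penalised Steiner trees and greedy
connectivity-significance expansion, checked against independent oracles."""

import itertools
import math
import random
from fractions import Fraction

import networkx as nx
import pytest

from netmedkit.errors import ConnectivityError, ParameterError, SeedError
from netmedkit.graph_model import SeedSet
from netmedkit.module_mining import (
    DiamondConfig,
    MustConfig,
    apply_hub_penalty,
    connectivity_pvalue,
    diamond,
    hub_penalized_weight,
    must,
    steiner_tree_approx,
)

from conftest import random_connected_graph


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def exact_hypergeom_tail(N, s0, k, ks) -> Fraction:
    """Exact upper-tail P(X >= ks) by direct combinatorial summation."""
    total = math.comb(N, k)
    acc = sum(math.comb(s0, j) * math.comb(N - s0, k - j)
              for j in range(ks, min(k, s0) + 1))
    return Fraction(acc, total)


def exhaustive_steiner_optimum(graph: nx.Graph, terminals) -> float:
    """Minimum Steiner tree cost by enumerating all node subsets (<= 12 nodes)."""
    terminals = set(terminals)
    others = sorted(set(graph.nodes) - terminals)
    best = math.inf
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            nodes = terminals | set(extra)
            sub = graph.subgraph(nodes)
            if sub.number_of_nodes() and nx.is_connected(sub):
                cost = sum(d.get("weight", 1.0)
                           for _, _, d in nx.minimum_spanning_tree(sub).edges(data=True))
                best = min(best, cost)
    return best


def reference_diamond(graph: nx.Graph, seeds, n_added):
    """Independent re-derivation of greedy expansion (alpha = 1): exact
    Fraction p-values, same documented tie-break."""
    N = graph.number_of_nodes()
    cluster = set(seeds)
    out = []
    for _ in range(n_added):
        s0 = len(cluster)
        cands = {n for m in cluster for n in graph.neighbors(m)} - cluster
        if not cands:
            break
        scored = []
        for c in sorted(cands):
            k = graph.degree(c)
            ks = sum(1 for n in graph.neighbors(c) if n in cluster)
            p = exact_hypergeom_tail(N, s0, k, ks)
            scored.append((p, -ks, k, c))
        p, nks, k, c = min(scored)
        cluster.add(c)
        out.append((c, float(p)))
    return out


# ---------------------------------------------------------------------------
# hub penalty
# ---------------------------------------------------------------------------

class TestHubPenalty:
    def test_zero_penalty_is_unit_weight(self):
        g = nx.path_graph(["a", "b", "c"])
        assert hub_penalized_weight(g, "a", "b", 0.0) == 1.0

    def test_regular_graph_always_unit(self):
        g = nx.cycle_graph(6)
        for lam in (0.0, 0.3, 1.0):
            assert hub_penalized_weight(g, 0, 1, lam) == pytest.approx(1.0)

    def test_full_penalty_hand_computed(self):
        # C4 plus the chord a-c: deg(a)=deg(c)=3, 5 edges over 4 nodes,
        # mean degree 2.5, so weight at lambda=1 is 6/5.
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")])
        assert hub_penalized_weight(g, "a", "c", 1.0) == pytest.approx(1.2)
        # affine blend at lambda=0.5
        assert hub_penalized_weight(g, "a", "c", 0.5) == pytest.approx(0.5 + 0.5 * 1.2)

    def test_monotone_in_degree_sum(self):
        g = nx.star_graph(5)  # center 0 degree 5, leaves degree 1
        g.add_edge(1, 2)
        w_hub = hub_penalized_weight(g, 0, 3, 0.7)
        w_leaf = hub_penalized_weight(g, 1, 2, 0.7)
        assert w_hub > w_leaf

    def test_out_of_range_penalty(self):
        g = nx.path_graph(3)
        with pytest.raises(ParameterError):
            hub_penalized_weight(g, 0, 1, 1.5)


# ---------------------------------------------------------------------------
# Steiner tree heuristic
# ---------------------------------------------------------------------------

class TestSteinerApprox:
    def test_adjacent_terminals(self):
        g = apply_hub_penalty(nx.Graph([("a", "b")]), 0.0)
        nodes, edges, cost = steiner_tree_approx(g, ["a", "b"])
        assert nodes == {"a", "b"} and edges == {("a", "b")} and cost == 1.0

    def test_path_through_steiner_node(self):
        g = apply_hub_penalty(nx.path_graph(["a", "x", "b"]), 0.0)
        nodes, edges, _ = steiner_tree_approx(g, ["a", "b"])
        assert nodes == {"a", "x", "b"} and len(edges) == 2

    def test_disconnected_terminals_listed(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        with pytest.raises(ConnectivityError, match="c"):
            steiner_tree_approx(g, ["a", "c"])

    def test_result_is_tree_spanning_terminals_with_terminal_leaves(self):
        rng = random.Random(7)
        for _ in range(20):
            g = random_connected_graph(rng, rng.randint(5, 14))
            nx.set_edge_attributes(g, 1.0, "weight")
            terms = rng.sample(sorted(g.nodes), rng.randint(2, 4))
            nodes, edges, _ = steiner_tree_approx(g, terms)
            t = nx.Graph(list(edges))
            t.add_nodes_from(nodes)
            assert nx.is_tree(t)
            assert set(terms) <= nodes
            for n in nodes:
                if t.degree(n) <= 1:
                    assert n in terms

    @pytest.mark.parametrize("seed", range(15))
    def test_cost_within_approximation_guarantee(self, seed):
        rng = random.Random(seed)
        n = rng.randint(6, 12)
        g = random_connected_graph(rng, n)
        for u, v in g.edges():
            g[u][v]["weight"] = rng.choice([1.0, 1.0, 2.0, 3.0])
        terms = rng.sample(sorted(g.nodes), rng.randint(3, 4))
        _, _, cost = steiner_tree_approx(g, terms)
        optimum = exhaustive_steiner_optimum(g, terms)
        ell = len(terms)
        assert cost <= 2.0 * (1.0 - 1.0 / ell) * optimum + 1e-9


# ---------------------------------------------------------------------------
# MuST
# ---------------------------------------------------------------------------

class TestMust:
    def test_two_adjacent_seeds(self):
        g = nx.Graph([("uniprot.A", "uniprot.B")])
        mod = must(g, SeedSet(("uniprot.A", "uniprot.B")), MustConfig())
        assert set(mod.members) == {"uniprot.A", "uniprot.B"}
        assert mod.n_components == 1

    def test_hub_penalty_keeps_module_off_hub(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("a", "h"), ("h", "b")])
        for i in range(48):
            g.add_edge("h", f"leaf{i}")
        mod = must(g, SeedSet(("a", "b")), MustConfig(hub_penalty=0.9, random_seed=1))
        assert "h" not in mod.members

    def test_single_tree_equals_heuristic_with_same_order(self):
        rng0 = random.Random(3)
        g = random_connected_graph(rng0, 12)
        nx.set_edge_attributes(g, 1.0, "weight")
        seeds = sorted(g.nodes)[:4]
        mod = must(g, SeedSet(tuple(seeds)), MustConfig(n_trees=1, random_seed=5))
        rng = random.Random("5:0:0")  # the per-tree stream for tree index 0
        order = list(seeds)
        rng.shuffle(order)
        nodes, _, _ = steiner_tree_approx(g, seeds, order)
        assert set(mod.members) == nodes

    def test_module_connected_and_contains_seeds(self):
        rng = random.Random(11)
        for _ in range(10):
            g = random_connected_graph(rng, rng.randint(8, 20))
            seeds = tuple(rng.sample(sorted(g.nodes), 3))
            mod = must(g, SeedSet(seeds), MustConfig(random_seed=2))
            assert mod.n_components == 1
            assert set(seeds) <= set(mod.members)

    def test_more_trees_never_remove_members(self):
        rng = random.Random(13)
        g = random_connected_graph(rng, 18)
        seeds = tuple(sorted(g.nodes)[:4])
        small = must(g, SeedSet(seeds), MustConfig(n_trees=3, random_seed=9, tolerance=1))
        large = must(g, SeedSet(seeds), MustConfig(n_trees=10, random_seed=9, tolerance=1))
        assert set(small.members) <= set(large.members)

    def test_disconnected_seeds_mined_per_component(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")])
        mod = must(g, SeedSet(("a", "c", "x", "z")), MustConfig())
        assert mod.n_components == 2
        assert set("abcxyz") == set(mod.members)

    def test_fewer_than_two_seeds_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(SeedError):
            must(g, SeedSet(("a",)), MustConfig())

    def test_deterministic_given_seed(self):
        rng = random.Random(17)
        g = random_connected_graph(rng, 25)
        seeds = tuple(rng.sample(sorted(g.nodes), 5))
        m1 = must(g, SeedSet(seeds), MustConfig(random_seed=4))
        m2 = must(g, SeedSet(seeds), MustConfig(random_seed=4))
        assert m1.members == m2.members


# ---------------------------------------------------------------------------
# connectivity significance
# ---------------------------------------------------------------------------

class TestConnectivityPvalue:
    def test_zero_links_gives_one(self):
        assert connectivity_pvalue(100, 10, 5, 0) == 1.0

    def test_hand_enumerated_values(self):
        # all C(10,2)=45 draws: 3 put both balls in the 3-node module
        assert connectivity_pvalue(10, 3, 2, 2) == pytest.approx(3 / 45, abs=1e-12)
        # >= 1 link: 1 - C(7,2)/C(10,2) = 24/45
        assert connectivity_pvalue(10, 3, 2, 1) == pytest.approx(24 / 45, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ParameterError):
            connectivity_pvalue(10, 3, 2, 3)

    @pytest.mark.parametrize("N", [5, 9, 17, 30])
    def test_agrees_with_exact_enumeration(self, N):
        for s0 in range(N + 1):
            for k in range(1, N + 1):
                for ks in range(min(k, s0) + 1):
                    exact = float(exact_hypergeom_tail(N, s0, k, ks))
                    assert connectivity_pvalue(N, s0, k, ks) == pytest.approx(
                        exact, abs=1e-12)

    def test_alpha_scales_module_counts(self):
        # alpha-fold module: s0 -> 2*s0, N -> N + s0
        assert connectivity_pvalue(10, 3, 2, 2, alpha=2) == pytest.approx(
            float(exact_hypergeom_tail(13, 6, 2, 2)), abs=1e-12)


# ---------------------------------------------------------------------------
# DIAMOnD greedy expansion
# ---------------------------------------------------------------------------

class TestDiamond:
    def test_no_expansion_returns_seeds(self):
        g = nx.path_graph(["a", "b", "c"])
        mod, added = diamond(g, SeedSet(("a", "b")), DiamondConfig(n_added=0))
        assert set(mod.members) == {"a", "b"} and added == []

    def test_candidate_with_more_seed_links_wins(self):
        # x touches both seeds, y touches one seed + a filler (equal degrees)
        g = nx.Graph([("s1", "x"), ("s2", "x"), ("s1", "y"), ("y", "z")])
        _, added = diamond(g, SeedSet(("s1", "s2")), DiamondConfig(n_added=1))
        assert added[0].node == "x"
        assert added[0].p < connectivity_pvalue(5, 2, 2, 1)

    def test_isolated_seeds_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("b", "c")
        from netmedkit.errors import IsolationError
        with pytest.raises(IsolationError):
            diamond(g, SeedSet(("a",)), DiamondConfig(n_added=1))

    def test_expansion_stops_when_no_candidates(self):
        g = nx.Graph([("a", "b")])
        g.add_node("far")
        mod, added = diamond(g, SeedSet(("a",)), DiamondConfig(n_added=10))
        assert set(mod.members) == {"a", "b"} and len(added) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_reimplementation(self, seed):
        rng = random.Random(seed)
        g = random_connected_graph(rng, rng.randint(20, 60), extra_edge_prob=0.08)
        seeds = tuple(rng.sample(sorted(g.nodes), 4))
        n_added = 8
        _, added = diamond(g, SeedSet(seeds), DiamondConfig(n_added=n_added))
        expected = reference_diamond(g, seeds, n_added)
        assert [a.node for a in added] == [c for c, _ in expected]
        for a, (_, p) in zip(added, expected):
            assert a.p == pytest.approx(p, abs=1e-12)

    def test_pvalues_recomputed_each_iteration(self):
        # after adding a node the module grows, so stored scores must reflect
        # the s0 at their own iteration, not a cached initial value
        g = nx.Graph([("s", "a"), ("s", "b"), ("a", "b"), ("b", "c")])
        _, added = diamond(g, SeedSet(("s",)), DiamondConfig(n_added=3))
        s0s = [a.s0 for a in added]
        assert s0s == sorted(s0s) and len(set(s0s)) == len(s0s)
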