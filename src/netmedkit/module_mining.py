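"""Disease-module identification on the PPI layer.

Two complementary miners are provided:

* **Multi-Steiner-tree mining** (``must``): approximates several low-cost
  Steiner trees connecting the seed proteins (terminals) under optionally
  hub-penalised edge weights, and aggregates their node sets into a single
  connected module.  Computing several trees instead of one stabilises the
  extracted mechanism because minimum Steiner trees are usually non-unique.

* **Greedy connectivity-significance expansion** (``diamond``): iteratively
  adds the node whose links into the current module are most significantly
  overrepresented under a hypergeometric null, one node per iteration, until
  the requested module size is reached.  The result need not be connected.

Both operate on an undirected protein–protein interaction graph (a
``networkx.Graph``), typically obtained from
:func:`netmedkit.graph_model.ppi_graph`.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
from scipy.stats import hypergeom

from .errors import ConnectivityError, IsolationError, ParameterError, SeedError
from .graph_model import SeedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseModule:
    """A mined module: protein members, the seeds it grew from, its induced
    PPI edges and the component count of the induced subgraph."""

    members: Tuple[str, ...]
    seeds: SeedSet
    induced_edges: Tuple[Tuple[str, str], ...]
    n_components: int
    provenance: str = ""

    def __post_init__(self):
        if not self.members:
            raise ParameterError("a disease module must have at least one member")
        missing = set(self.seeds.ids) - set(self.members)
        if missing:
            raise ParameterError(f"seeds not contained in members: {sorted(missing)}")

    @classmethod
    def from_graph(cls, graph: nx.Graph, members: Iterable[str], seeds: SeedSet,
                   provenance: str = "") -> "DiseaseModule":
        members = tuple(dict.fromkeys(members))
        sub = graph.subgraph(members)
        edges = tuple(sorted(tuple(sorted(e)) for e in sub.edges()))
        return cls(members, seeds, edges, nx.number_connected_components(sub), provenance)


@dataclass(frozen=True)
class MustConfig:
    """Parameters of the multi-Steiner-tree miner.

    ``n_trees``: how many approximate Steiner trees to aggregate.
    ``hub_penalty``: lambda in [0, 1]; 0 gives unit edge weights, larger
    values penalise routing through high-degree proteins.
    ``tolerance``: extra cost (in edge-weight units) an alternative tree may
    have over the best tree found so far and still be accepted.
    """

    n_trees: int = 10
    hub_penalty: float = 0.0
    tolerance: float = 0.0
    random_seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")
        if not 0.0 <= self.hub_penalty <= 1.0:
            raise ParameterError("hub_penalty must lie in [0, 1]")
        if self.tolerance < 0:
            raise ParameterError("tolerance must be non-negative")


@dataclass(frozen=True)
class DiamondConfig:
    """Parameters of the greedy expansion: number of nodes to add and the
    integer seed weight alpha (1 = seeds count like ordinary members)."""

    n_added: int = 0
    alpha: int = 1
    random_seed: int = 0

    def __post_init__(self):
        if self.n_added < 0:
            raise ParameterError("n_added must be >= 0")
        if self.alpha < 1:
            raise ParameterError("alpha must be a positive integer")


@dataclass(frozen=True)
class ConnectivityScore:
    """Hypergeometric connectivity significance of one candidate node."""

    node: str
    k: int          # degree in the network (alpha-weighted if alpha > 1)
    ks: int         # links into the current module (alpha-weighted)
    p: float        # upper-tail hypergeometric probability
    N: int          # network node count used
    s0: int         # module size used


# ---------------------------------------------------------------------------
# Hub-penalised edge weights
# ---------------------------------------------------------------------------

def hub_penalized_weight(graph: nx.Graph, u: str, v: str, hub_penalty: float) -> float:
    """Edge weight (1 - lam) + lam * (deg(u) + deg(v)) / (2 * mean degree).

    lam = 0 gives unit weights; for lam > 0 the weight grows with the
    endpoint degree sum, so shortest paths avoid hubs.  On a regular graph
    every weight is exactly 1 for any lam.
    """
    if not 0.0 <= hub_penalty <= 1.0:
        raise ParameterError("hub_penalty must lie in [0, 1]")
    if not graph.has_edge(u, v):
        raise ParameterError(f"no PPI edge between {u!r} and {v!r}")
    if hub_penalty == 0.0:
        return 1.0
    mean_deg = 2.0 * graph.number_of_edges() / graph.number_of_nodes()
    return (1.0 - hub_penalty) + hub_penalty * (graph.degree(u) + graph.degree(v)) / (2.0 * mean_deg)


def apply_hub_penalty(graph: nx.Graph, hub_penalty: float) -> nx.Graph:
    """Copy of ``graph`` with a ``weight`` attribute on every edge."""
    g = graph.copy()
    if hub_penalty == 0.0:
        nx.set_edge_attributes(g, 1.0, "weight")
        return g
    mean_deg = 2.0 * g.number_of_edges() / g.number_of_nodes()
    for u, v in g.edges():
        g[u][v]["weight"] = (1.0 - hub_penalty) + hub_penalty * (
            g.degree(u) + g.degree(v)) / (2.0 * mean_deg)
    return g


# ---------------------------------------------------------------------------
# Steiner tree approximation (shortest-path insertion heuristic)
# ---------------------------------------------------------------------------

def steiner_tree_approx(graph: nx.Graph, terminals: Sequence[str],
                        order: Optional[Sequence[str]] = None,
                        ) -> Tuple[Set[str], Set[Tuple[str, str]], float]:
    """Approximate minimum-cost tree connecting ``terminals``.

    Shortest-path insertion: start from the first terminal of ``order``,
    repeatedly attach the (weighted-)nearest unconnected terminal to the
    growing tree along a minimum-weight shortest path, then prune
    non-terminal leaves.  The classical guarantee of this heuristic is a
    cost within ``2 * (1 - 1/l)`` of the optimum for ``l`` terminals.

    Returns ``(node set, edge set, cost)`` with edges as sorted pairs.
    """
    terminals = list(dict.fromkeys(terminals))
    if order is None:
        order = terminals
    else:
        order = list(order)
        if sorted(order) != sorted(terminals):
            raise ParameterError("order must be a permutation of the terminals")
    if not terminals:
        raise SeedError("at least one terminal is required")
    for t in terminals:
        if t not in graph:
            raise ConnectivityError(f"terminal {t!r} is not in the PPI layer", [t])

    unreachable = [t for t in terminals[1:]
                   if not nx.has_path(graph, terminals[0], t)]
    if unreachable:
        raise ConnectivityError(
            "terminals span multiple components; unreachable from "
            f"{terminals[0]!r}: {sorted(unreachable)}", unreachable)

    tree = nx.Graph()
    tree.add_node(order[0])
    remaining = [t for t in order[1:]]

    while remaining:
        # sorted sources keep shortest-path tie-breaking reproducible
        dist, paths = nx.multi_source_dijkstra(graph, sorted(tree.nodes), weight="weight")
        # nearest unconnected terminal; ties broken by insertion order
        best_t, best_d = None, None
        for t in remaining:
            d = dist.get(t)
            if d is None:
                continue
            if best_d is None or d < best_d:
                best_t, best_d = t, d
        path = paths[best_t]
        for a, b in zip(path, path[1:]):
            tree.add_edge(a, b, weight=graph[a][b].get("weight", 1.0))
        remaining.remove(best_t)

    # prune non-terminal leaves (can arise when paths overlap)
    terminal_set = set(terminals)
    changed = True
    while changed:
        changed = False
        for n in list(tree.nodes):
            if tree.degree(n) == 1 and n not in terminal_set:
                tree.remove_node(n)
                changed = True

    cost = sum(d.get("weight", 1.0) for _, _, d in tree.edges(data=True))
    edges = {tuple(sorted(e)) for e in tree.edges()}
    return set(tree.nodes), edges, cost


# ---------------------------------------------------------------------------
# MuST: aggregate several approximate Steiner trees
# ---------------------------------------------------------------------------

def must(graph: nx.Graph, seeds: SeedSet, config: MustConfig = MustConfig()) -> DiseaseModule:
    """Multi-Steiner-tree disease module.

    ``n_trees`` trees are built with distinct random terminal-insertion
    orders (tree ``i`` uses an RNG derived from ``(random_seed, i)``, so the
    first trees are identical whatever ``n_trees`` is).  A tree is accepted
    if its cost does not exceed the best cost found so far by more than
    ``tolerance``; the module is the union of accepted tree node sets.

    Seeds spread over several components are handled per component (with a
    warning); the resulting module then has more than one component.
    """
    present = [s for s in seeds if s in graph]
    absent = [s for s in seeds if s not in graph]
    if absent:
        logger.warning("seeds absent from PPI layer ignored: %s", ", ".join(absent))
    if len(present) < 2:
        raise SeedError(f"MuST needs >= 2 seeds on the PPI layer, got {len(present)}")

    g = apply_hub_penalty(graph, config.hub_penalty)

    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            comp_of[n] = ci
    groups: Dict[int, List[str]] = {}
    for s in present:
        groups.setdefault(comp_of[s], []).append(s)
    if len(groups) > 1:
        logger.warning("seeds span %d components; mining per component", len(groups))

    members: List[str] = []
    for ci in sorted(groups):
        terminals = groups[ci]
        if len(terminals) == 1:
            members.append(terminals[0])
            continue
        best_cost = None
        accepted: List[Set[str]] = []
        for i in range(config.n_trees):
            rng = random.Random(f"{config.random_seed}:{ci}:{i}")
            order = list(terminals)
            rng.shuffle(order)
            nodes, _, cost = steiner_tree_approx(g, terminals, order)
            if best_cost is None or cost < best_cost:
                best_cost = cost
            if cost <= best_cost + config.tolerance:
                accepted.append(nodes)
        union: Set[str] = set()
        for nodes in accepted:
            union |= nodes
        members.extend(sorted(union))

    prov = (f"must(n_trees={config.n_trees}, hub_penalty={config.hub_penalty}, "
            f"tolerance={config.tolerance}, random_seed={config.random_seed})")
    return DiseaseModule.from_graph(graph, members, SeedSet(tuple(present), seeds.origin), prov)


# ---------------------------------------------------------------------------
# DIAMOnD: connectivity significance and greedy expansion
# ---------------------------------------------------------------------------

def connectivity_pvalue(N: int, s0: int, k: int, ks: int, alpha: int = 1) -> float:
    """Hypergeometric upper-tail probability of >= ``ks`` links into a module.

    ``p = sum_{j=ks}^{min(k, s0)} C(s0, j) C(N - s0, k - j) / C(N, k)`` for a
    node of degree ``k`` in an ``N``-node network containing a module of
    ``s0`` nodes.  ``alpha > 1`` counts the module ``alpha``-fold
    (``s0 -> alpha*s0``, ``N -> N + (alpha-1)*s0``); callers that weight
    individual seed links pass pre-weighted counts with ``alpha=1``.
    """
    if alpha < 1:
        raise ParameterError("alpha must be a positive integer")
    if alpha > 1:
        N = N + (alpha - 1) * s0
        s0 = alpha * s0
    if not (0 <= s0 <= N and 0 <= k <= N):
        raise ParameterError(f"inconsistent counts: N={N}, s0={s0}, k={k}")
    if ks < 0 or ks > min(k, s0):
        raise ParameterError(f"ks={ks} outside [0, min(k={k}, s0={s0})]")
    if ks == 0:
        return 1.0
    p = float(hypergeom.sf(ks - 1, N, s0, k))
    return min(max(p, 5e-324), 1.0)


def diamond(graph: nx.Graph, seeds: SeedSet, config: DiamondConfig = DiamondConfig(),
            ) -> Tuple[DiseaseModule, List[ConnectivityScore]]:
    """Greedy module expansion by connectivity significance.

    Every iteration scores each non-member node adjacent to the current
    module by :func:`connectivity_pvalue` and adds the most significant one;
    ties break by (smaller p, larger ks, smaller k, lexicographic id).  Seed
    links and seed contribution to the module size count ``alpha``-fold.
    Runs ``n_added`` iterations or until no candidate has a link into the
    module.  The returned module may be disconnected.
    """
    present = [s for s in seeds if s in graph]
    if not present:
        raise SeedError("no seed is present in the PPI layer")
    if all(graph.degree(s) == 0 for s in present):
        raise IsolationError("no seed has any PPI edge; cannot expand a module")

    alpha = config.alpha
    seed_set = set(present)
    N = graph.number_of_nodes() + (alpha - 1) * len(seed_set)

    cluster: Set[str] = set(present)
    added: List[ConnectivityScore] = []

    for _ in range(config.n_added):
        s0 = len(cluster) + (alpha - 1) * len(seed_set & cluster)
        candidates: Set[str] = set()
        for m in cluster:
            candidates.update(graph.neighbors(m))
        candidates -= cluster
        if not candidates:
            break

        best: Optional[Tuple[float, int, int, str]] = None
        best_score: Optional[ConnectivityScore] = None
        for node in candidates:
            nbrs = set(graph.neighbors(node))
            kb = len(nbrs & cluster)
            kb_seed = len(nbrs & seed_set & cluster)
            ks = kb + (alpha - 1) * kb_seed
            k = graph.degree(node) + (alpha - 1) * kb_seed
            p = connectivity_pvalue(N, s0, k, ks)
            key = (p, -ks, k, node)
            if best is None or key < best:
                best = key
                best_score = ConnectivityScore(node, k, ks, p, N, s0)
        cluster.add(best_score.node)
        added.append(best_score)

    members = list(present) + [a.node for a in added]
    prov = f"diamond(n_added={config.n_added}, alpha={alpha})"
    module = DiseaseModule.from_graph(graph, members, SeedSet(tuple(present), seeds.origin), prov)
    return module, added


def write_module_tsv(module: DiseaseModule, added: Optional[List[ConnectivityScore]], path) -> None:
    """TSV export: node id, is_seed, added_rank, p_value."""
    rank = {a.node: (i + 1, a.p) for i, a in enumerate(added or [])}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tis_seed\tadded_rank\tp_value\n")
        for m in module.members:
            is_seed = "true" if m in module.seeds else "false"
            r, p = rank.get(m, ("", ""))
            fh.write(f"{m}\t{is_seed}\t{r}\t{p}\n")
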