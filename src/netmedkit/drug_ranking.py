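"""Drug prioritisation against a seed set.

Both rankers run on the *ranking graph*: the union of the experimental
protein–protein interaction layer and the drug–target layer, with unit edge
weights.  Genes and diseases never enter this graph.

* **TrustRank**: personalised PageRank in which trust originates uniformly
  from the seed proteins and is propagated along edges with damping factor
  ``d``; drugs well connected to the seeds accumulate trust.
* **Seed-restricted closeness**: harmonic closeness computed with respect to
  the seeds only — a drug scores the sum of reciprocal shortest-path
  distances to the seeds, so drugs a short distance from the disease module
  rank first.  Unreachable seeds contribute 0.

Candidate modes: *direct* drugs target a seed protein themselves; *indirect*
drugs are any drug connected to the seeds' component (their targets lie in
the seeds' vicinity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import ParameterError, SeedError
from .graph_model import HetNet, SeedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedDrugList:
    """Ordered (drug id, score, 1-based rank) entries; zero scores excluded.

    Scores are non-increasing with rank; ties receive distinct ranks by
    lexicographic drug id."""

    entries: Tuple[Tuple[str, float, int], ...]
    algorithm: str
    seeds_used: SeedSet

    def ids(self) -> List[str]:
        return [e[0] for e in self.entries]

    def top(self, k: int) -> "RankedDrugList":
        return RankedDrugList(self.entries[:k], self.algorithm, self.seeds_used)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class TrustRankConfig:
    damping: float = 0.85
    tolerance: float = 1e-6
    max_iterations: int = 100
    approved_only: bool = False
    include_indirect: bool = True

    def __post_init__(self):
        if not 0.0 <= self.damping <= 1.0:
            raise ParameterError("damping must lie in [0, 1]")
        if self.tolerance < 0 or self.max_iterations < 1:
            raise ParameterError("tolerance must be >= 0 and max_iterations >= 1")


@dataclass(frozen=True)
class ClosenessConfig:
    approved_only: bool = False
    include_indirect: bool = True
    #: "harmonic" sums reciprocal distances to seeds; "classic" is
    #: |reachable seeds| / (sum of distances to them).
    variant: str = "harmonic"

    def __post_init__(self):
        if self.variant not in ("harmonic", "classic"):
            raise ParameterError("variant must be 'harmonic' or 'classic'")


def ranking_graph(net: HetNet, approved_only: bool = False) -> nx.Graph:
    """Undirected graph over proteins + drugs: experimental PPI edges plus
    drug_target edges, unit weights; non-approved drugs dropped on request."""
    g = nx.Graph()
    for n in net.nodes:
        if n.kind == "protein":
            g.add_node(n.id, kind="protein")
        elif n.kind == "drug":
            if approved_only and "approved" not in n.attributes.get("groups", "").split("|"):
                continue
            g.add_node(n.id, kind="drug")
    for e in net.edges_of_kind("ppi"):
        if e.attributes.get("evidence", "experimental") == "experimental":
            g.add_edge(e.source, e.target)
    for e in net.edges_of_kind("drug_target"):
        if g.has_node(e.source):
            g.add_edge(e.source, e.target)
    return g


def candidate_drugs(net: HetNet, seeds: SeedSet, include_indirect: bool = False,
                    approved_only: bool = False,
                    graph: Optional[nx.Graph] = None) -> Set[str]:
    """Drugs eligible for ranking.

    direct mode: drugs with a drug_target edge onto a seed protein.
    indirect mode: every drug in the same ranking-graph component as a seed
    (exactly the drugs that can attain a nonzero ranking score).
    """
    if graph is None:
        graph = ranking_graph(net, approved_only=approved_only)
    seed_set = {s for s in seeds if graph.has_node(s)}
    if not include_indirect:
        direct = set()
        for e in net.edges_of_kind("drug_target"):
            if e.target in seed_set and graph.has_node(e.source):
                direct.add(e.source)
        return direct
    reachable: Set[str] = set()
    seen: Set[str] = set()
    for s in seed_set:
        if s in seen:
            continue
        comp = nx.node_connected_component(graph, s)
        seen |= comp
        reachable |= {n for n in comp if graph.nodes[n].get("kind") == "drug"}
    return reachable


def _finalize(scores: Dict[str, float], candidates: Set[str], algorithm: str,
              seeds: SeedSet) -> RankedDrugList:
    kept = [(d, s) for d, s in scores.items() if d in candidates and s > 0.0]
    kept.sort(key=lambda t: (-t[1], t[0]))
    entries = tuple((d, s, i + 1) for i, (d, s) in enumerate(kept))
    return RankedDrugList(entries, algorithm, seeds)


def trustrank(net: HetNet, seeds: SeedSet, config: TrustRankConfig = TrustRankConfig(),
              ) -> RankedDrugList:
    """Rank drugs by propagated trust from the seed proteins.

    Solves ``t = d * W t + (1 - d) * t0`` by power iteration with ``W`` the
    column-normalised adjacency of the ranking graph and ``t0`` uniform over
    the seeds.  Columns with no edges (isolated nodes) redistribute their
    mass to ``t0``.  Iteration stops once the L1 change drops below
    ``tolerance`` or after ``max_iterations`` (with a logged warning).
    """
    graph = ranking_graph(net, approved_only=config.approved_only)
    order = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(order)}
    seed_idx = [index[s] for s in seeds if s in index]
    if not seed_idx:
        raise SeedError("no seed protein is present in the ranking graph")

    n = len(order)
    adj = nx.to_scipy_sparse_array(graph, nodelist=order, format="csc", dtype=float)
    degrees = np.asarray(adj.sum(axis=0)).ravel()
    inv_deg = np.divide(1.0, degrees, out=np.zeros_like(degrees), where=degrees > 0)
    W = adj @ sp.diags(inv_deg)
    dangling = degrees == 0

    t0 = np.zeros(n)
    t0[seed_idx] = 1.0 / len(seed_idx)
    d = config.damping

    t = t0.copy()
    converged = False
    for _ in range(config.max_iterations):
        t_new = d * (W @ t + t[dangling].sum() * t0) + (1 - d) * t0
        if np.abs(t_new - t).sum() < config.tolerance:
            t = t_new
            converged = True
            break
        t = t_new
    if not converged:
        logger.warning("TrustRank did not converge within %d iterations; "
                       "returning last iterate", config.max_iterations)

    scores = {node: float(t[i]) for node, i in index.items()
              if graph.nodes[node].get("kind") == "drug"}
    candidates = candidate_drugs(net, seeds, config.include_indirect,
                                 config.approved_only, graph=graph)
    algo = (f"trustrank(damping={d}, approved_only={config.approved_only}, "
            f"include_indirect={config.include_indirect})")
    return _finalize(scores, candidates, algo, seeds)


def closeness(net: HetNet, seeds: SeedSet, config: ClosenessConfig = ClosenessConfig(),
              ) -> RankedDrugList:
    """Rank drugs by closeness to the seed proteins.

    Harmonic variant (default): ``C(v) = sum over reachable seeds s of
    1 / d(v, s)`` with unweighted shortest-path distances in the ranking
    graph.  Classic variant: ``|reachable seeds| / sum of distances``.
    """
    graph = ranking_graph(net, approved_only=config.approved_only)
    seed_list = [s for s in seeds if graph.has_node(s)]
    if not seed_list:
        raise SeedError("no seed protein is present in the ranking graph")

    inv_sum: Dict[str, float] = {}
    dist_sum: Dict[str, float] = {}
    n_reach: Dict[str, int] = {}
    for s in seed_list:
        lengths = nx.single_source_shortest_path_length(graph, s)
        for node, dist in lengths.items():
            if graph.nodes[node].get("kind") != "drug" or dist == 0:
                continue
            inv_sum[node] = inv_sum.get(node, 0.0) + 1.0 / dist
            dist_sum[node] = dist_sum.get(node, 0.0) + dist
            n_reach[node] = n_reach.get(node, 0) + 1

    if config.variant == "harmonic":
        scores = inv_sum
    else:
        scores = {v: n_reach[v] / dist_sum[v] for v in dist_sum}

    candidates = candidate_drugs(net, seeds, config.include_indirect,
                                 config.approved_only, graph=graph)
    algo = (f"closeness(variant={config.variant}, approved_only={config.approved_only}, "
            f"include_indirect={config.include_indirect})")
    return _finalize(scores, candidates, algo, seeds)


def exclude_seed_targeting(ranked: RankedDrugList, exclude: SeedSet, net: HetNet,
                           ) -> RankedDrugList:
    """Drop drugs *all* of whose targets lie inside ``exclude``; re-rank."""
    excluded = set(exclude.ids)
    targets: Dict[str, Set[str]] = {}
    for e in net.edges_of_kind("drug_target"):
        targets.setdefault(e.source, set()).add(e.target)
    kept = [(d, s) for d, s, _ in ranked.entries
            if targets.get(d, set()) - excluded]
    entries = tuple((d, s, i + 1) for i, (d, s) in enumerate(kept))
    return RankedDrugList(entries, ranked.algorithm + " | exclude_seed_targeting",
                          ranked.seeds_used)


def write_ranked_tsv(ranked: RankedDrugList, net: HetNet, path,
                     top_k: Optional[int] = None) -> None:
    """TSV export: rank, drug id, label, score, targets_in_seeds count."""
    seed_set = set(ranked.seeds_used.ids)
    targets: Dict[str, Set[str]] = {}
    for e in net.edges_of_kind("drug_target"):
        targets.setdefault(e.source, set()).add(e.target)
    entries = ranked.entries if top_k is None else ranked.entries[:top_k]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdrug\tlabel\tscore\ttargets_in_seeds\n")
        for drug, score, rank in entries:
            label = net.node(drug).label if net.has_node(drug) else ""
            n_in = len(targets.get(drug, set()) & seed_set)
            fh.write(f"{rank}\t{drug}\t{label}\t{score:.12g}\t{n_in}\n")
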