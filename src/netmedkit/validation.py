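"""Empirical statistical validation of modules and ranked drug lists.

Three permutation schemes, all reporting an empirical p-value as the
fraction ``r/n`` of null draws whose statistic *strictly exceeds* the
observed one (reported as ``"< 1/n"`` when ``r = 0``, e.g. "< 0.001" at
1000 permutations):

a) **Drug-list validation** — compare the discounted cumulative gain (or
   plain overlap) of a ranked drug list against equally long random drug
   lists drawn from a pool.
b) **Module validation** — compare the precision (or intersection size) of
   the drugs targeting a module against mock modules that match the observed
   module's size and number of connected components.
c) **Joint validation** — re-run the whole ranking pipeline from each mock
   module and compare list precisions, so both pipeline stages enter the
   null.

Also provides the one-sided hypergeometric test for the overlap of two gene
sets.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
from scipy.stats import hypergeom

from .errors import InputError, ParameterError, SamplingError
from .graph_model import HetNet, SeedSet, drugs_targeting
from .module_mining import DiseaseModule
from .drug_ranking import RankedDrugList

import math


@dataclass(frozen=True)
class ReferenceDrugs:
    """Ground-truth drugs (e.g. indicated for the disease under scrutiny)."""

    ids: frozenset
    source: str = "user file"

    def __post_init__(self):
        object.__setattr__(self, "ids", frozenset(self.ids))
        if not self.ids:
            raise InputError("reference drug list must be non-empty")

    @classmethod
    def from_indications(cls, net: HetNet, disease: str) -> "ReferenceDrugs":
        """Drugs with a drug_indication edge to ``disease``."""
        ids = {e.source for e in net.edges_of_kind("drug_indication")
               if e.target == disease}
        return cls(frozenset(ids), source=f"network drug_indication edges for {disease}")


@dataclass(frozen=True)
class EmpiricalResult:
    """Observed statistic, permutation count n, exceedance count r, p = r/n."""

    statistic_observed: float
    n_permutations: int
    n_exceeding: int
    p: float
    reported: str
    mode: str = ""

    def as_dict(self) -> Dict:
        return {
            "statistic_observed": self.statistic_observed,
            "n_permutations": self.n_permutations,
            "n_exceeding": self.n_exceeding,
            "p": self.p,
            "reported": self.reported,
            "mode": self.mode,
        }


@dataclass(frozen=True)
class MockModuleSpec:
    """Constraints a mock module must match: the observed module's component
    sizes (hence its size and component count)."""

    component_sizes: Tuple[int, ...]
    random_seed: int = 0

    def __post_init__(self):
        if not self.component_sizes or any(s < 1 for s in self.component_sizes):
            raise ParameterError("component sizes must be positive integers")

    @classmethod
    def from_module(cls, module: DiseaseModule, random_seed: int = 0) -> "MockModuleSpec":
        g = nx.Graph()
        g.add_nodes_from(module.members)
        g.add_edges_from(module.induced_edges)
        sizes = tuple(sorted((len(c) for c in nx.connected_components(g)), reverse=True))
        return cls(sizes, random_seed)


def _empirical(observed: float, null_stats: Iterable[float], mode: str,
               strict: bool = True) -> EmpiricalResult:
    null_stats = list(null_stats)
    n = len(null_stats)
    if n == 0:
        raise ParameterError("n_permutations must be >= 1")
    if strict:
        r = sum(1 for s in null_stats if s > observed)
    else:
        r = sum(1 for s in null_stats if s >= observed)
    p = r / n
    reported = f"< {1.0 / n:g}" if r == 0 else f"= {p:g}"
    return EmpiricalResult(observed, n, r, p, reported, mode)


# ---------------------------------------------------------------------------
# Method a: ranked drug lists
# ---------------------------------------------------------------------------

def dcg(ranked_ids: Sequence[str], reference: ReferenceDrugs) -> float:
    """Discounted cumulative gain: sum of 1/log2(i+1) over reference hits at
    1-based rank i."""
    if len(set(ranked_ids)) != len(ranked_ids):
        raise InputError("ranked drug list contains duplicates")
    ref = reference.ids
    return sum(1.0 / math.log2(i + 1)
               for i, d in enumerate(ranked_ids, start=1) if d in ref)


def overlap(ranked_ids: Sequence[str], reference: ReferenceDrugs) -> float:
    """Plain hit count (rank-insensitive simplification of the DCG)."""
    if len(set(ranked_ids)) != len(ranked_ids):
        raise InputError("ranked drug list contains duplicates")
    return float(sum(1 for d in ranked_ids if d in reference.ids))


_LIST_STATS: Dict[str, Callable[[Sequence[str], ReferenceDrugs], float]] = {
    "dcg": dcg,
    "overlap": overlap,
}


def validate_drug_list(ranked: RankedDrugList, reference: ReferenceDrugs,
                       pool: Iterable[str], n_permutations: int = 1000,
                       mode: str = "dcg", random_seed: int = 0,
                       strict: bool = True) -> EmpiricalResult:
    """Empirical p-value of a ranked drug list vs random lists from ``pool``.

    Draws ``n_permutations`` uniformly random ordered lists of the same
    length (sampling without replacement within each list) and counts how
    many attain a strictly greater statistic than the observed list.
    """
    if mode not in _LIST_STATS:
        raise ParameterError(f"mode must be one of {sorted(_LIST_STATS)}")
    pool = sorted(set(pool))
    ids = ranked.ids()
    if len(ids) > len(pool):
        raise SamplingError(
            f"pool of {len(pool)} drugs is smaller than the ranked list ({len(ids)})")
    stat = _LIST_STATS[mode]
    observed = stat(ids, reference)
    rng = random.Random(random_seed)
    null = (stat(rng.sample(pool, len(ids)), reference) for _ in range(n_permutations))
    return _empirical(observed, null, mode, strict)


# ---------------------------------------------------------------------------
# Method b: disease modules vs topology-matched mock modules
# ---------------------------------------------------------------------------

def sample_mock_module(graph: nx.Graph, spec: MockModuleSpec,
                       rng: Optional[random.Random] = None,
                       max_retries: int = 100) -> DiseaseModule:
    """Random connected node sets matching the spec's component sizes.

    Each component grows from a uniformly chosen start node by repeatedly
    adding a uniformly chosen boundary neighbour; components are kept
    mutually non-adjacent so the induced subgraph has exactly the requested
    number of components.  Dead ends trigger a retry (bounded).
    """
    if rng is None:
        rng = random.Random(spec.random_seed)
    nodes = sorted(graph.nodes)
    if max(spec.component_sizes) > len(nodes):
        raise SamplingError("requested component larger than the network")

    for _ in range(max_retries):
        used: Set[str] = set()
        forbidden: Set[str] = set()
        components: List[List[str]] = []
        ok = True
        for size in spec.component_sizes:
            grown = _grow_component(graph, size, forbidden, rng, max_retries)
            if grown is None:
                ok = False
                break
            components.append(grown)
            used |= set(grown)
            forbidden |= set(grown)
            for n in grown:
                forbidden.update(graph.neighbors(n))
        if ok:
            members = tuple(sorted(used))
            return DiseaseModule.from_graph(
                graph, members, SeedSet((), origin="mock"), provenance="mock module")
    raise SamplingError(
        f"could not sample a mock module matching component sizes "
        f"{list(spec.component_sizes)} after {max_retries} attempts")


def _grow_component(graph: nx.Graph, size: int, forbidden: Set[str],
                    rng: random.Random, max_retries: int) -> Optional[List[str]]:
    allowed = sorted(set(graph.nodes) - forbidden)
    if len(allowed) < size:
        return None
    for _ in range(max_retries):
        start = rng.choice(allowed)
        comp = {start}
        boundary = sorted(set(graph.neighbors(start)) - forbidden)
        while len(comp) < size:
            boundary = [b for b in boundary if b not in comp]
            if not boundary:
                break
            pick = rng.choice(boundary)
            comp.add(pick)
            boundary.extend(sorted(set(graph.neighbors(pick)) - forbidden - comp))
        if len(comp) == size:
            return sorted(comp)
    return None


def module_precision(module: DiseaseModule, net: HetNet, reference: ReferenceDrugs,
                     mode: str = "precision") -> float:
    """Precision = |targeting drugs ∩ reference| / |targeting drugs| (0 when
    nothing targets the module); intersection = the raw overlap count."""
    targeting = set(drugs_targeting(net, module.members))
    hits = len(targeting & reference.ids)
    if mode == "intersection":
        return float(hits)
    if mode == "precision":
        return hits / len(targeting) if targeting else 0.0
    raise ParameterError("mode must be 'precision' or 'intersection'")


def validate_module(module: DiseaseModule, net: HetNet, reference: ReferenceDrugs,
                    graph: Optional[nx.Graph] = None, n_permutations: int = 1000,
                    mode: str = "precision", random_seed: int = 0,
                    strict: bool = True) -> EmpiricalResult:
    """Empirical p-value of a module's precision vs topology-matched mocks."""
    if graph is None:
        from .graph_model import ppi_graph
        graph = ppi_graph(net)
    spec = MockModuleSpec.from_module(module, random_seed)
    observed = module_precision(module, net, reference, mode)
    rng = random.Random(random_seed)
    null = (
        module_precision(sample_mock_module(graph, spec, rng), net, reference, mode)
        for _ in range(n_permutations)
    )
    return _empirical(observed, null, mode, strict)


# ---------------------------------------------------------------------------
# Method c: joint validation of module + ranking
# ---------------------------------------------------------------------------

def list_precision(ranked_ids: Sequence[str], reference: ReferenceDrugs) -> float:
    """Reference drugs contained in the list divided by the list length."""
    if not ranked_ids:
        return 0.0
    return sum(1 for d in ranked_ids if d in reference.ids) / len(ranked_ids)


def validate_joint(module: DiseaseModule, net: HetNet, reference: ReferenceDrugs,
                   rank_fn: Callable[[HetNet, SeedSet], RankedDrugList],
                   graph: Optional[nx.Graph] = None, n_permutations: int = 1000,
                   mode: str = "precision", random_seed: int = 0,
                   top_k: Optional[int] = None, strict: bool = True) -> EmpiricalResult:
    """Empirical p-value over the whole pipeline: for the observed module and
    each mock module, rank drugs with the members as seeds (``rank_fn``) and
    compare list precisions (or intersection sizes)."""
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    if mode not in ("precision", "intersection"):
        raise ParameterError("mode must be 'precision' or 'intersection'")
    if graph is None:
        from .graph_model import ppi_graph
        graph = ppi_graph(net)

    def statistic(members: Sequence[str]) -> float:
        ranked = rank_fn(net, SeedSet(tuple(members), origin="module"))
        ids = ranked.ids() if top_k is None else ranked.ids()[:top_k]
        if mode == "intersection":
            return float(sum(1 for d in ids if d in reference.ids))
        return list_precision(ids, reference)

    spec = MockModuleSpec.from_module(module, random_seed)
    observed = statistic(module.members)
    rng = random.Random(random_seed)
    null = (
        statistic(sample_mock_module(graph, spec, rng).members)
        for _ in range(n_permutations)
    )
    return _empirical(observed, null, mode, strict)


# ---------------------------------------------------------------------------
# Hypergeometric overlap of two gene sets
# ---------------------------------------------------------------------------

def hypergeom_overlap_test(set_a: Iterable[str], set_b: Iterable[str],
                           universe: int) -> float:
    """One-sided p-value P(X >= |A∩B|) for X ~ Hypergeom(N=universe,
    K=|A|, n=|B|): the chance two random sets of these sizes overlap at
    least as much."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe or len(b) > universe:
        raise ParameterError("set sizes exceed the universe size")
    k = len(a & b)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, universe, len(a), len(b)))
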