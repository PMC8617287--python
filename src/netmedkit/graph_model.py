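"""Typed heterogeneous network model with readers, writers and queries.

The in-memory container for networks over four node kinds (gene, protein,
drug, disease) and six edge kinds.  Node identifiers are namespaced strings
of the form ``{namespace}.{identifier}`` (``entrez.1017``,
``uniprot.P51587``, ``drugbank.DB00945``, ``mondo.0005011``).  All edge
kinds are undirected except ``disease_hierarchy``, which is directed from
child to parent disease.

The module also houses the disease-centric queries used by the pipeline:
collecting disease-associated genes (optionally through the disease
hierarchy), mapping gene seeds onto the protein layer, projecting the PPI
layer, and finding the drugs that target a protein set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import networkx as nx
from lxml import etree

from .errors import (
    GraphMLParseError,
    ReferentialError,
    SchemaError,
    SeedError,
    UnknownNodeError,
)

logger = logging.getLogger(__name__)

NODE_KINDS = frozenset({"gene", "protein", "drug", "disease"})

#: edge kind -> (kind of one endpoint, kind of the other). For directed
#: ``disease_hierarchy`` the order is (child, parent).
EDGE_ENDPOINT_KINDS: Mapping[str, Tuple[str, str]] = {
    "ppi": ("protein", "protein"),
    "drug_target": ("drug", "protein"),
    "gene_disease": ("gene", "disease"),
    "drug_indication": ("drug", "disease"),
    "gene_protein": ("gene", "protein"),
    "disease_hierarchy": ("disease", "disease"),
}

DIRECTED_EDGE_KINDS = frozenset({"disease_hierarchy"})


@dataclass(frozen=True)
class NodeRecord:
    """A typed node: namespaced ``id``, ``kind``, display ``label``, attributes."""

    id: str
    kind: str
    label: str = ""
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise SchemaError(
                f"node {self.id!r}: unknown kind {self.kind!r} "
                f"(expected one of {sorted(NODE_KINDS)})"
            )
        ns, dot, _ = self.id.partition(".")
        if not dot or not ns or not ns.islower():
            raise SchemaError(
                f"node {self.id!r}: id must be namespaced as "
                "'{namespace}.{identifier}' with a lowercase namespace"
            )
        object.__setattr__(self, "attributes", dict(self.attributes))


@dataclass(frozen=True)
class EdgeRecord:
    """A typed edge. ``source``/``target`` order is canonicalised on insert
    for undirected kinds; for ``disease_hierarchy`` it is child -> parent."""

    source: str
    target: str
    kind: str
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EDGE_ENDPOINT_KINDS:
            raise SchemaError(
                f"edge {self.source!r}->{self.target!r}: unknown kind {self.kind!r}"
            )
        if self.source == self.target:
            raise SchemaError(f"edge {self.source!r}: self-loops are not allowed")
        object.__setattr__(self, "attributes", dict(self.attributes))

    @property
    def key(self) -> Tuple[str, str, str]:
        """Uniqueness key: one edge of a given kind per unordered pair."""
        if self.kind in DIRECTED_EDGE_KINDS:
            return (self.kind, self.source, self.target)
        a, b = sorted((self.source, self.target))
        return (self.kind, a, b)


@dataclass(frozen=True)
class SeedSet:
    """An ordered, duplicate-free set of gene/protein ids with provenance."""

    ids: Tuple[str, ...]
    origin: str = "user file"

    def __post_init__(self):
        seen, ordered = set(), []
        for i in self.ids:
            if i not in seen:
                seen.add(i)
                ordered.append(i)
        object.__setattr__(self, "ids", tuple(ordered))

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in set(self.ids)


class HetNet:
    """A heterogeneous network: typed nodes plus typed edges.

    Nodes are keyed by id; at most one edge of a given kind exists per
    unordered node pair.  Duplicate edge insertions collapse to the first
    occurrence (a warning is logged).  Equality compares node and edge sets
    including attributes, which is what makes round-trip tests meaningful.
    """

    def __init__(self, nodes: Iterable[NodeRecord] = (), edges: Iterable[EdgeRecord] = ()):
        self._nodes: Dict[str, NodeRecord] = {}
        self._edges: Dict[Tuple[str, str, str], EdgeRecord] = {}
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    # -- construction ------------------------------------------------------

    def add_node(self, node: NodeRecord) -> None:
        if node.id in self._nodes and self._nodes[node.id] != node:
            raise SchemaError(f"node id {node.id!r} inserted twice with differing records")
        self._nodes[node.id] = node

    def add_edge(self, edge: EdgeRecord) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self._nodes:
                raise ReferentialError(
                    f"edge of kind {edge.kind!r} references missing node id {endpoint!r}"
                )
        want = EDGE_ENDPOINT_KINDS[edge.kind]
        got = (self._nodes[edge.source].kind, self._nodes[edge.target].kind)
        if edge.kind in DIRECTED_EDGE_KINDS:
            if got != want:
                raise SchemaError(
                    f"edge kind {edge.kind!r} requires {want[0]}->{want[1]} endpoints, "
                    f"got {got[0]}->{got[1]} ({edge.source!r}->{edge.target!r})"
                )
        else:
            if tuple(sorted(got)) != tuple(sorted(want)):
                raise SchemaError(
                    f"edge kind {edge.kind!r} requires {want} endpoints, got {got} "
                    f"({edge.source!r}--{edge.target!r})"
                )
            # canonical orientation: source takes the first declared kind
            if got != want:
                edge = EdgeRecord(edge.target, edge.source, edge.kind, edge.attributes)
            elif want[0] == want[1] and edge.source > edge.target:
                edge = EdgeRecord(edge.target, edge.source, edge.kind, edge.attributes)
        if edge.key in self._edges:
            logger.warning(
                "duplicate %s edge %s--%s ignored (first occurrence kept)",
                edge.kind, edge.source, edge.target,
            )
            return
        self._edges[edge.key] = edge

    # -- access ------------------------------------------------------------

    @property
    def nodes(self) -> List[NodeRecord]:
        return [self._nodes[i] for i in sorted(self._nodes)]

    @property
    def edges(self) -> List[EdgeRecord]:
        return [self._edges[k] for k in sorted(self._edges)]

    def node(self, node_id: str) -> NodeRecord:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownNodeError(f"unknown node id {node_id!r}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node_ids(self, kind: Optional[str] = None) -> List[str]:
        if kind is None:
            return sorted(self._nodes)
        return sorted(i for i, n in self._nodes.items() if n.kind == kind)

    def edges_of_kind(self, kind: str) -> List[EdgeRecord]:
        return [e for k, e in sorted(self._edges.items()) if k[0] == kind]

    def __eq__(self, other) -> bool:
        if not isinstance(other, HetNet):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"HetNet(|nodes|={len(self._nodes)}, |edges|={len(self._edges)})"

    def to_networkx(self, kinds: Iterable[str], node_kinds: Iterable[str]) -> nx.Graph:
        """Undirected simple graph over the selected node/edge kinds."""
        g = nx.Graph()
        node_kinds = set(node_kinds)
        kinds = set(kinds)
        for n in self.nodes:
            if n.kind in node_kinds:
                g.add_node(n.id, kind=n.kind)
        for e in self.edges:
            if e.kind in kinds and g.has_node(e.source) and g.has_node(e.target):
                g.add_edge(e.source, e.target, kind=e.kind)
        return g


# ---------------------------------------------------------------------------
# GraphML I/O
#
# Dialect: node/edge attributes as <data> elements referring to declared
# <key> elements; reserved key names "kind", "label", "groups", "evidence".
# The graph element is edgedefault="undirected"; disease_hierarchy edges are
# emitted with directed="true" (GraphML mixed-graph convention).
# ---------------------------------------------------------------------------

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_graphml(net: HetNet, path) -> None:
    """Serialise ``net`` so that :func:`read_graphml` reconstructs it exactly."""
    nsmap = {None: _GRAPHML_NS}
    root = etree.Element(f"{{{_GRAPHML_NS}}}graphml", nsmap=nsmap)

    node_attr_names = sorted({k for n in net.nodes for k in n.attributes} | {"kind", "label"})
    edge_attr_names = sorted({k for e in net.edges for k in e.attributes} | {"kind"})

    key_ids: Dict[Tuple[str, str], str] = {}
    counter = 0
    for domain, names in (("node", node_attr_names), ("edge", edge_attr_names)):
        for name in names:
            kid = f"d{counter}"
            counter += 1
            key_ids[(domain, name)] = kid
            key = etree.SubElement(root, f"{{{_GRAPHML_NS}}}key")
            key.set("id", kid)
            key.set("for", domain)
            key.set("attr.name", name)
            key.set("attr.type", "string")

    graph = etree.SubElement(root, f"{{{_GRAPHML_NS}}}graph")
    graph.set("edgedefault", "undirected")

    def put(parent, domain, name, value):
        d = etree.SubElement(parent, f"{{{_GRAPHML_NS}}}data")
        d.set("key", key_ids[(domain, name)])
        d.text = value

    for n in net.nodes:
        el = etree.SubElement(graph, f"{{{_GRAPHML_NS}}}node")
        el.set("id", n.id)
        put(el, "node", "kind", n.kind)
        if n.label:
            put(el, "node", "label", n.label)
        for k in sorted(n.attributes):
            put(el, "node", k, n.attributes[k])

    for e in net.edges:
        el = etree.SubElement(graph, f"{{{_GRAPHML_NS}}}edge")
        el.set("source", e.source)
        el.set("target", e.target)
        if e.kind in DIRECTED_EDGE_KINDS:
            el.set("directed", "true")
        put(el, "edge", "kind", e.kind)
        for k in sorted(e.attributes):
            put(el, "edge", k, e.attributes[k])

    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_graphml(path) -> HetNet:
    """Parse a GraphML file into a :class:`HetNet`, validating the schema.

    Unknown attribute keys are preserved verbatim on the records.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GraphMLParseError(
            f"malformed GraphML in {path}: {exc.msg} (line {exc.lineno})"
        ) from exc
    root = tree.getroot()

    keys: Dict[str, Tuple[str, str]] = {}
    for key in root.iter(f"{{{_GRAPHML_NS}}}key"):
        keys[key.get("id")] = (key.get("for", "all"), key.get("attr.name", key.get("id")))

    def collect(el) -> Dict[str, str]:
        data = {}
        for d in el.findall(f"{{{_GRAPHML_NS}}}data"):
            ref = d.get("key")
            name = keys.get(ref, ("all", ref))[1]
            data[name] = d.text or ""
        return data

    net = HetNet()
    graph = root.find(f"{{{_GRAPHML_NS}}}graph")
    if graph is None:
        raise GraphMLParseError(f"{path}: no <graph> element found")

    for el in graph.findall(f"{{{_GRAPHML_NS}}}node"):
        nid = el.get("id")
        data = collect(el)
        kind = data.pop("kind", None)
        if kind is None:
            raise SchemaError(f"node {nid!r}: missing required 'kind' attribute")
        label = data.pop("label", "")
        net.add_node(NodeRecord(nid, kind, label, data))

    for el in graph.findall(f"{{{_GRAPHML_NS}}}edge"):
        src, tgt = el.get("source"), el.get("target")
        data = collect(el)
        kind = data.pop("kind", None)
        if kind is None:
            raise SchemaError(f"edge {src!r}->{tgt!r}: missing required 'kind' attribute")
        net.add_edge(EdgeRecord(src, tgt, kind, data))

    return net


# ---------------------------------------------------------------------------
# TSV node/edge tables
# ---------------------------------------------------------------------------

def read_edge_tables(node_table, edge_table) -> HetNet:
    """Load a network from two tab-separated tables.

    ``node_table`` columns: id, kind, label, then attribute columns.
    ``edge_table`` columns: source, target, kind, then attribute columns.
    Empty attribute cells are treated as absent.
    """
    import csv

    net = HetNet()
    with open(node_table, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "kind"}
        if not required <= set(reader.fieldnames or ()):
            raise SchemaError(f"{node_table}: node table must have columns id, kind")
        for row in reader:
            attrs = {
                k: v for k, v in row.items()
                if k not in ("id", "kind", "label") and v not in (None, "")
            }
            net.add_node(NodeRecord(row["id"], row["kind"], row.get("label") or "", attrs))

    missing: List[str] = []
    pending: List[EdgeRecord] = []
    with open(edge_table, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"source", "target", "kind"}
        if not required <= set(reader.fieldnames or ()):
            raise SchemaError(f"{edge_table}: edge table must have columns source, target, kind")
        for row in reader:
            attrs = {
                k: v for k, v in row.items()
                if k not in ("source", "target", "kind") and v not in (None, "")
            }
            for endpoint in (row["source"], row["target"]):
                if not net.has_node(endpoint):
                    missing.append(endpoint)
            pending.append(EdgeRecord(row["source"], row["target"], row["kind"], attrs))
    if missing:
        raise ReferentialError(
            "edge table references missing node ids: " + ", ".join(sorted(set(missing)))
        )
    for e in pending:
        net.add_edge(e)
    return net


def write_edge_tables(net: HetNet, node_table, edge_table) -> None:
    """Inverse of :func:`read_edge_tables` (column superset of all attributes)."""
    import csv

    node_attr_names = sorted({k for n in net.nodes for k in n.attributes})
    with open(node_table, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "kind", "label"] + node_attr_names)
        for n in net.nodes:
            w.writerow([n.id, n.kind, n.label] + [n.attributes.get(k, "") for k in node_attr_names])

    edge_attr_names = sorted({k for e in net.edges for k in e.attributes})
    with open(edge_table, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["source", "target", "kind"] + edge_attr_names)
        for e in net.edges:
            w.writerow(
                [e.source, e.target, e.kind]
                + [e.attributes.get(k, "") for k in edge_attr_names]
            )


def read_id_list(path) -> List[str]:
    """One id per line; blank lines and '#' comments ignored."""
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return ids


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def get_disease_genes(net: HetNet, disease: str, include_descendants: bool = False) -> SeedSet:
    """Genes associated with a disease, optionally via the disease hierarchy.

    With ``include_descendants`` the query also collects genes associated
    with every disease reachable from ``disease`` by reversed
    child->parent hierarchy edges (i.e. all of its descendants).
    """
    if not net.has_node(disease) or net.node(disease).kind != "disease":
        raise UnknownNodeError(f"unknown disease id {disease!r}")

    diseases = {disease}
    if include_descendants:
        children: Dict[str, List[str]] = {}
        for e in net.edges_of_kind("disease_hierarchy"):
            children.setdefault(e.target, []).append(e.source)
        stack = [disease]
        while stack:
            d = stack.pop()
            for c in children.get(d, ()):
                if c not in diseases:
                    diseases.add(c)
                    stack.append(c)

    genes = set()
    for e in net.edges_of_kind("gene_disease"):
        if e.target in diseases:
            genes.add(e.source)
    return SeedSet(tuple(sorted(genes)), origin="disease query")


def map_seeds_to_proteins(net: HetNet, seeds: SeedSet) -> SeedSet:
    """Lift gene/protein seeds onto the protein layer.

    Protein seeds pass through; gene seeds map along gene_protein edges
    (many-to-many allowed, union taken).  Genes encoding no protein are
    logged as dropped.  An empty result is an error because downstream
    algorithms require at least one seed on the PPI layer.
    """
    encoded: Dict[str, List[str]] = {}
    for e in net.edges_of_kind("gene_protein"):
        encoded.setdefault(e.source, []).append(e.target)

    proteins, dropped = [], []
    for sid in seeds:
        rec = net.node(sid)
        if rec.kind == "protein":
            proteins.append(sid)
        elif rec.kind == "gene":
            targets = encoded.get(sid, [])
            if targets:
                proteins.extend(sorted(targets))
            else:
                dropped.append(sid)
        else:
            raise SeedError(f"seed {sid!r} has kind {rec.kind!r}; expected gene or protein")
    if dropped:
        logger.warning("dropped %d gene seed(s) without encoded protein: %s",
                       len(dropped), ", ".join(dropped))
    if not proteins:
        raise SeedError("no seed could be mapped to the protein layer")
    return SeedSet(tuple(proteins), origin=f"mapped from {seeds.origin}")


def project_ppi(net: HetNet, experimental_only: bool = True) -> HetNet:
    """The protein–protein interaction layer as its own network.

    Keeps every protein node (isolated ones included); with
    ``experimental_only`` (the default, matching how the mining algorithms
    are meant to be run) only edges whose ``evidence`` is experimental
    survive.
    """
    out = HetNet()
    for n in net.nodes:
        if n.kind == "protein":
            out.add_node(n)
    for e in net.edges_of_kind("ppi"):
        if experimental_only and e.attributes.get("evidence", "experimental") != "experimental":
            continue
        out.add_edge(e)
    return out


def ppi_graph(net: HetNet, experimental_only: bool = True) -> nx.Graph:
    """networkx view of the PPI layer (same filter as :func:`project_ppi`)."""
    g = nx.Graph()
    for n in net.nodes:
        if n.kind == "protein":
            g.add_node(n.id)
    for e in net.edges_of_kind("ppi"):
        if experimental_only and e.attributes.get("evidence", "experimental") != "experimental":
            continue
        g.add_edge(e.source, e.target)
    return g


def drugs_targeting(net: HetNet, proteins: Iterable[str], approved_only: bool = False) -> List[str]:
    """Drugs with at least one drug_target edge into ``proteins`` (sorted by id)."""
    member = set(proteins)
    drugs = set()
    for e in net.edges_of_kind("drug_target"):
        if e.target in member:
            drugs.add(e.source)
    if approved_only:
        drugs = {
            d for d in drugs
            if "approved" in net.node(d).attributes.get("groups", "").split("|")
        }
    return sorted(drugs)
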