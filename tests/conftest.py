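"""Shared fixtures: small hand-built heterogeneous networks and random
network generators used across the suite."""

import random

import networkx as nx
import pytest

from netmedkit.graph_model import EdgeRecord, HetNet, NodeRecord


def make_hetnet(nodes, edges):
    """nodes: (id, kind[, label[, attrs]]), edges: (src, tgt, kind[, attrs])."""
    net = HetNet()
    for spec in nodes:
        nid, kind = spec[0], spec[1]
        label = spec[2] if len(spec) > 2 else ""
        attrs = spec[3] if len(spec) > 3 else {}
        net.add_node(NodeRecord(nid, kind, label, attrs))
    for spec in edges:
        src, tgt, kind = spec[0], spec[1], spec[2]
        attrs = spec[3] if len(spec) > 3 else {}
        net.add_edge(EdgeRecord(src, tgt, kind, attrs))
    return net


@pytest.fixture
def toy_net():
    """A small network exercising every node and edge kind.

    PPI layer: p1-p2-p3 path plus p3-p4 (predicted evidence); genes g1..g4
    encode p1..p4 (g2 additionally encodes p3); disease hierarchy
    child -> parent; drugs with targets and one indication.
    """
    return make_hetnet(
        nodes=[
            ("uniprot.P1", "protein", "P1"),
            ("uniprot.P2", "protein", "P2"),
            ("uniprot.P3", "protein", "P3"),
            ("uniprot.P4", "protein", "P4"),
            ("entrez.1", "gene", "G1"),
            ("entrez.2", "gene", "G2"),
            ("entrez.3", "gene", "G3"),
            ("entrez.4", "gene", "G4"),
            ("mondo.0001", "disease", "parent disease"),
            ("mondo.0002", "disease", "child disease"),
            ("drugbank.DB01", "drug", "DrugA", {"groups": "approved"}),
            ("drugbank.DB02", "drug", "DrugB", {"groups": "other"}),
        ],
        edges=[
            ("uniprot.P1", "uniprot.P2", "ppi", {"evidence": "experimental"}),
            ("uniprot.P2", "uniprot.P3", "ppi", {"evidence": "experimental"}),
            ("uniprot.P3", "uniprot.P4", "ppi", {"evidence": "predicted"}),
            ("entrez.1", "uniprot.P1", "gene_protein"),
            ("entrez.2", "uniprot.P2", "gene_protein"),
            ("entrez.2", "uniprot.P3", "gene_protein"),
            ("entrez.3", "uniprot.P3", "gene_protein"),
            ("entrez.4", "uniprot.P4", "gene_protein"),
            ("mondo.0002", "mondo.0001", "disease_hierarchy"),
            ("entrez.1", "mondo.0001", "gene_disease"),
            ("entrez.2", "mondo.0002", "gene_disease"),
            ("entrez.3", "mondo.0002", "gene_disease"),
            ("drugbank.DB01", "uniprot.P1", "drug_target"),
            ("drugbank.DB02", "uniprot.P1", "drug_target"),
            ("drugbank.DB01", "mondo.0001", "drug_indication"),
        ],
    )


def random_hetnet(rng: random.Random, n_proteins: int = 8, n_drugs: int = 3,
                  n_diseases: int = 2):
    """A random schema-valid heterogeneous network for round-trip tests."""
    proteins = [f"uniprot.R{i}" for i in range(n_proteins)]
    genes = [f"entrez.{100 + i}" for i in range(n_proteins)]
    drugs = [f"drugbank.RX{i}" for i in range(n_drugs)]
    diseases = [f"mondo.{900 + i}" for i in range(n_diseases)]
    nodes = (
        [(p, "protein", f"prot {p}") for p in proteins]
        + [(g, "gene", f"gene {g}") for g in genes]
        + [(d, "drug", f"drug {d}",
            {"groups": rng.choice(["approved", "other", "approved|other"])})
           for d in drugs]
        + [(d, "disease", f"disease {d}") for d in diseases]
    )
    edges = [(genes[i], proteins[i], "gene_protein") for i in range(n_proteins)]
    for i in range(n_proteins):
        for j in range(i + 1, n_proteins):
            if rng.random() < 0.4:
                edges.append((proteins[i], proteins[j], "ppi",
                              {"evidence": rng.choice(["experimental", "predicted"])}))
    for d in drugs:
        for p in rng.sample(proteins, rng.randint(1, 3)):
            edges.append((d, p, "drug_target"))
        if rng.random() < 0.5:
            edges.append((d, rng.choice(diseases), "drug_indication"))
    for g in rng.sample(genes, 3):
        edges.append((g, rng.choice(diseases), "gene_disease"))
    if n_diseases >= 2:
        edges.append((diseases[1], diseases[0], "disease_hierarchy"))
    return make_hetnet(nodes, edges)


def random_connected_graph(rng: random.Random, n: int, extra_edge_prob: float = 0.25,
                           ) -> nx.Graph:
    """Connected labelled graph: random spanning tree plus extra edges."""
    names = [f"uniprot.N{i:02d}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(names)
    order = names[:]
    rng.shuffle(order)
    for i in range(1, n):
        g.add_edge(order[i], rng.choice(order[:i]))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < extra_edge_prob:
                g.add_edge(names[i], names[j])
    return g
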