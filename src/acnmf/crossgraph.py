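"""Cross-dataset program graph.

Programs discovered independently in different datasets (patient cohorts,
cell lines, xenografts, mouse models) are compared pairwise through an
asymmetric Jaccard overlap test: each dataset contributes the top-J genes
of each program at its own tuned Jaccard length, the universe is the
intersection of the datasets' gene lists, and edges are kept at a
Bonferroni-controlled family-wise error rate. Communities of the
resulting graph (walktrap random walks, cut at maximum modularity) group
programs replicated across datasets; a Fruchterman-Reingold layout and
GraphML/JSON export support downstream visualization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np

from .rank_select import jaccard_test, top_genes

__all__ = [
    "ProgramCatalog",
    "cross_edges",
    "build_program_graph",
    "detect_graph_communities",
    "layout_graph",
    "export_graph",
    "import_graph",
]


@dataclass
class ProgramCatalog:
    """One dataset's programs: gene-weight table plus its tuned Jaccard length."""

    dataset_id: str
    gene_ids: np.ndarray
    weights: np.ndarray  # genes x n_programs (Z-scored or raw; ranks are what matter)
    program_ids: list
    tuned_J: int

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(self.program_ids) != len(set(self.program_ids)):
            raise ValueError("duplicate program ids")
        if self.tuned_J > len(self.gene_ids):
            raise ValueError("tuned_J exceeds gene universe")

    def top_sets(self, universe: set) -> list[frozenset]:
        """Top tuned_J gene sets, restricted to a shared universe."""
        keep = np.array([g in universe for g in self.gene_ids])
        gids = self.gene_ids[keep]
        sets = []
        for p in range(self.weights.shape[1]):
            J = min(self.tuned_J, len(gids))
            sets.append(frozenset(top_genes(self.weights[keep, p], J, gids)))
        return sets


def cross_edges(catalogs: list[ProgramCatalog], alpha_fwer: float = 0.05):
    """Significant cross-dataset program pairs at Bonferroni FWER < alpha.

    The test is asymmetric in that each dataset contributes sets of its
    own tuned size; the universe is the intersection of all catalog gene
    lists. Returns edges ``((ds_a, prog_a), (ds_b, prog_b), result)``;
    the edge set does not depend on catalog order.
    """
    if len(catalogs) < 2:
        raise ValueError("need at least 2 catalogs")
    universe = set(catalogs[0].gene_ids)
    for c in catalogs[1:]:
        universe &= set(c.gene_ids)
    if not universe:
        raise ValueError("empty shared gene universe")
    G = len(universe)
    cats = sorted(catalogs, key=lambda c: c.dataset_id)
    sets = {c.dataset_id: c.top_sets(universe) for c in cats}
    n_tests = 0
    pairs = []
    for a in range(len(cats)):
        for b in range(a + 1, len(cats)):
            ca, cb = cats[a], cats[b]
            for i, sa in enumerate(sets[ca.dataset_id]):
                for j, sb in enumerate(sets[cb.dataset_id]):
                    n_tests += 1
                    pairs.append((ca, i, sa, cb, j, sb))
    edges = []
    for ca, i, sa, cb, j, sb in pairs:
        res = jaccard_test(sa, sb, G)
        res.p_adjusted = min(1.0, res.p_raw * n_tests)
        if res.p_adjusted < alpha_fwer:
            edges.append(
                ((ca.dataset_id, ca.program_ids[i]), (cb.dataset_id, cb.program_ids[j]), res)
            )
    return edges


def build_program_graph(catalogs, alpha_fwer: float = 0.05) -> nx.Graph:
    """Assemble the attributed cross-dataset graph (all programs as nodes)."""
    g = nx.Graph()
    for c in catalogs:
        for pid in c.program_ids:
            g.add_node((c.dataset_id, pid), dataset=c.dataset_id, program=str(pid))
    for u, v, res in cross_edges(catalogs, alpha_fwer=alpha_fwer):
        g.add_edge(u, v, jaccard_index=res.jaccard_index, p_adjusted=res.p_adjusted)
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree[n]
    return g


def detect_graph_communities(graph: nx.Graph, walk_steps: int = 4, seed: int = 0) -> dict:
    """Walktrap communities cut at maximum modularity; isolated nodes are singletons."""
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(graph.nodes, key=str))}
    nodes = sorted(graph.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    connected = [n for n in nodes if graph.degree[n] > 0]
    sub = ig.Graph(
        n=len(connected),
        edges=[
            (connected.index(u), connected.index(v)) for u, v in graph.edges
        ],
    )
    clustering = sub.community_walktrap(steps=walk_steps).as_clustering()
    labels = {}
    for ci, members in enumerate(clustering):
        for m in members:
            labels[connected[m]] = ci
    next_label = len(clustering)
    for n in nodes:
        if n not in labels:
            labels[n] = next_label
            next_label += 1
    return labels


def layout_graph(graph: nx.Graph, seed: int = 0, iterations: int = 100) -> dict:
    """Seeded Fruchterman-Reingold (force-directed) 2-D layout."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_nodes() == 1:
        return {n: np.zeros(2) for n in graph.nodes}
    pos = nx.spring_layout(graph, seed=seed, iterations=iterations)
    return {n: np.asarray(p, dtype=float) for n, p in pos.items()}


def _flatten(n):
    return "|".join(str(x) for x in n) if isinstance(n, tuple) else str(n)


def export_graph(graph: nx.Graph, path, format: str = "graphml", layout: dict | None = None) -> None:
    """Lossless export of nodes, edges, attributes and optional layout."""
    g = nx.relabel_nodes(graph, {n: _flatten(n) for n in graph.nodes}, copy=True)
    if layout is not None:
        for n, p in layout.items():
            g.nodes[_flatten(n)]["x"], g.nodes[_flatten(n)]["y"] = float(p[0]), float(p[1])
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "json":
        data = nx.node_link_data(g, edges="edges")
        path.write_text(json.dumps(data, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


def import_graph(path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "json":
        return nx.node_link_graph(json.loads(path.read_text()), edges="edges")
    raise ValueError(f"unknown format {format!r}")
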