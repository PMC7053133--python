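"""Pathway graphs and distance-rule subpathway mining.

A pathway is an undirected graph whose nodes are genes.  A *subpathway* is a
maximal set of genes in which every pair lies within shortest-path distance
``k`` of each other (default ``k = 3``) — equivalently, a maximal clique of
the graph's k-th power.  Nodes in different connected components are at
infinite distance and never share a subpathway.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd

from .datatypes import DataError, FeatureSet, PATHWAY, SUBPATHWAY


class PathwayGraph:
    """An undirected gene graph with a pathway identifier.

    Self-loops are dropped; edge endpoints are implicitly declared as nodes.
    Extra isolated nodes may be supplied via ``nodes``.
    """

    def __init__(self, id: str, edges, nodes=()) -> None:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u != v:
                g.add_edge(u, v)
        if g.number_of_nodes() == 0:
            raise DataError(f"pathway {id!r}: empty graph")
        self.id = id
        self.graph = g

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @classmethod
    def from_edge_table(cls, id: str, table: pd.DataFrame) -> "PathwayGraph":
        """Build from a two-column edge table (extra columns ignored)."""
        if table.shape[1] < 2:
            raise DataError(f"pathway {id!r}: edge table needs >= 2 columns")
        pairs = table.iloc[:, :2].astype(str).itertuples(index=False, name=None)
        return cls(id, list(pairs))

    def as_feature_set(self) -> FeatureSet:
        return FeatureSet(id=self.id, level=PATHWAY, genes=frozenset(map(str, self.nodes)))


def _graph_power(g: nx.Graph, k: int) -> nx.Graph:
    """Graph with an edge wherever shortest-path distance <= k."""
    p = nx.Graph()
    p.add_nodes_from(g.nodes)
    for src, dist in nx.all_pairs_shortest_path_length(g, cutoff=k):
        for dst in dist:
            if dst != src:
                p.add_edge(src, dst)
    return p


def mine_subpathways(graph: PathwayGraph, k: int = 3) -> list[FeatureSet]:
    """All maximal gene sets with pairwise distance <= ``k`` in ``graph``.

    Computed as the maximal cliques of the k-th graph power.  Output order is
    deterministic — descending size, then lexicographically smallest member —
    and subpathway ids are ``<pathway id>_<1-based rank>`` in that order.
    Isolated nodes yield singleton subpathways.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    power = _graph_power(graph.graph, k)
    cliques = [frozenset(map(str, c)) for c in nx.find_cliques(power)]
    cliques.sort(key=lambda c: (-len(c), min(c), sorted(c)))
    return [
        FeatureSet(id=f"{graph.id}_{i}", level=SUBPATHWAY, genes=c, parent=graph.id)
        for i, c in enumerate(cliques, start=1)
    ]


def brute_force_subpathways(graph: PathwayGraph, k: int = 3) -> list[frozenset[str]]:
    """Reference enumeration for small graphs (exponential; <= ~15 nodes).

    Enumerates every node subset, keeps those whose pairwise distances are all
    <= ``k``, and filters to maximal ones.  Used as an independent oracle for
    :func:`mine_subpathways`.
    """
    g = graph.graph
    nodes = sorted(g.nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    ok: list[frozenset[str]] = []
    for r in range(1, len(nodes) + 1):
        for combo in combinations(nodes, r):
            good = all(
                v in dist[u] and dist[u][v] <= k for u, v in combinations(combo, 2)
            )
            if good:
                ok.append(frozenset(combo))
    maximal = [s for s in ok if not any(s < t for t in ok)]
    maximal.sort(key=lambda c: (-len(c), min(c), sorted(c)))
    return maximal


def shared_genes(a: FeatureSet, b: FeatureSet) -> set[str]:
    """Genes common to two feature sets (overlap utility)."""
    return set(a.genes & b.genes)
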