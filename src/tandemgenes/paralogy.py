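"""Paralogous-group construction from a protein similarity table.

A similarity graph is built from pairwise hits passing an E-value cutoff
(reciprocal support optional), and paralogous groups are its connected
components with at least two members.  Precomputed orthogroup files can
be supplied instead, so clustering output from heavier tools drops in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .model import GroupSet, SimilarityHit

DEFAULT_MAX_EVALUE = 1e-5


@dataclass
class SimilarityGraph:
    """Undirected gene-similarity graph; edge weight is the max bitscore
    over supporting hits."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def build_similarity_graph(
    hits: Iterable[SimilarityHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    reciprocal: bool = True,
) -> SimilarityGraph:
    """Self-hits are dropped.  An edge (a, b) requires an a->b hit with
    evalue <= max_evalue; with ``reciprocal`` a qualifying b->a hit is
    also required.  All genes seen in any hit become nodes, so isolated
    genes survive as singletons."""
    if max_evalue <= 0:
        raise ValueError("max_evalue must be > 0")
    g = nx.Graph()
    qualifying: dict[tuple[str, str], float] = {}  # directed pair -> best bitscore
    for h in hits:
        g.add_node(h.query_id)
        g.add_node(h.subject_id)
        if h.query_id == h.subject_id:
            continue
        if h.evalue <= max_evalue:
            key = (h.query_id, h.subject_id)
            qualifying[key] = max(qualifying.get(key, float("-inf")), h.bitscore)
    for (a, b), score in qualifying.items():
        if reciprocal:
            back = qualifying.get((b, a))
            if back is None:
                continue
            weight = max(score, back)
        else:
            weight = max(score, qualifying.get((b, a), float("-inf")))
        if g.has_edge(a, b):
            weight = max(weight, g[a][b]["weight"])
        g.add_edge(a, b, weight=weight)
    return SimilarityGraph(graph=g)


def cluster_paralogs(graph: SimilarityGraph) -> GroupSet:
    """Connected components with >= 2 nodes become groups; isolated
    nodes are singletons (not groups).  Group ids are PG%06d assigned in
    descending component size, ties broken by the lexicographically
    smallest member, so output is permutation-invariant."""
    components = [sorted(c) for c in nx.connected_components(graph.graph) if len(c) >= 2]
    components.sort(key=lambda c: (-len(c), c[0]))
    gs = GroupSet()
    for i, comp in enumerate(components, start=1):
        gs.add(f"PG{i:06d}", [("sp", gene) for gene in comp])
    return gs


def singleton_nodes(graph: SimilarityGraph) -> set[str]:
    """Nodes with no qualifying edge."""
    return {n for n in graph.graph.nodes if graph.graph.degree(n) == 0}


def family_partition(
    member_genes: set[str], groups: GroupSet
) -> tuple[int, int, int]:
    """Partition a labelled gene set (e.g. all P450s) into clusters and
    singletons.

    A group counts as a cluster only if >= 2 of its members carry the
    label (restricted-subgroup rule); label-set genes in no counted
    cluster are singletons.  Returns (n_clusters, n_cluster_genes,
    n_singletons) with n_cluster_genes + n_singletons == |member_genes|.
    """
    n_clusters = 0
    clustered: set[str] = set()
    for members in groups.groups.values():
        inside = {g for _, g in members} & member_genes
        if len(inside) >= 2:
            n_clusters += 1
            clustered |= inside
    n_singletons = len(member_genes - clustered)
    return n_clusters, len(clustered), n_singletons
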