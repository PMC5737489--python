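"""Tandem duplicated gene-cluster detection.

A tandem cluster is a maximal chained set of genes that (i) share a
paralogous/orthologous group, (ii) lie on one scaffold with no more
than ``max_intervening`` annotated genes between any linked pair
(inclusive bound), and (iii) have pairwise gene distance strictly below
``max_distance``.  Pairs satisfying (ii) and (iii) within a (group,
scaffold) restriction are linked, and clusters are the connected
components of those links — so a run of k pairwise-near co-group genes
yields one cluster of size k.

Distance is the intergenic gap by default (bp between the facing ends
of the two genes, 0 for overlaps); start-to-start distance is available
because the criterion's exact definition varies between tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx

from .model import GeneRecord, GroupSet

DistanceMode = Literal["intergenic", "start_to_start"]


@dataclass
class TandemParams:
    max_intervening: int = 10
    max_distance: int = 100_000  # strict upper bound, bp
    min_members: int = 2
    distance_mode: DistanceMode = "intergenic"

    def __post_init__(self) -> None:
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if self.min_members < 2:
            raise ValueError("min_members must be >= 2")
        if self.distance_mode not in ("intergenic", "start_to_start"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")


@dataclass
class TandemCluster:
    cluster_id: str
    group_id: str
    scaffold_id: str
    member_gene_ids: list[str]  # sorted by start coordinate
    span_bp: int  # end of last member - start of first + 1

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


def assign_gene_order(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Assign per-scaffold 0-based rank by (start, end, gene_id); strand
    is ignored.  Returns the records sorted by (scaffold, rank).
    Identical (scaffold, start, end, id) duplicates are a hard error."""
    seen: set[tuple[str, int, int, str]] = set()
    for g in genes:
        key = (g.scaffold_id, g.start, g.end, g.gene_id)
        if key in seen:
            raise ValueError(f"duplicate gene record {key}")
        seen.add(key)
    ordered = sorted(genes, key=lambda g: (g.scaffold_id, g.start, g.end, g.gene_id))
    rank = 0
    prev_scaffold: str | None = None
    for g in ordered:
        if g.scaffold_id != prev_scaffold:
            rank = 0
            prev_scaffold = g.scaffold_id
        g.rank = rank
        rank += 1
    return ordered


def intervening_count(a: GeneRecord, b: GeneRecord) -> int:
    """Number of annotated genes strictly between two genes on one
    scaffold, counted over ALL genes regardless of group membership."""
    if a.scaffold_id != b.scaffold_id:
        raise ValueError(
            f"genes {a.gene_id}/{b.gene_id} are on different scaffolds"
        )
    if a.rank < 0 or b.rank < 0:
        raise ValueError("ranks not assigned; call assign_gene_order first")
    return abs(a.rank - b.rank) - 1


def gene_distance(a: GeneRecord, b: GeneRecord, mode: DistanceMode = "intergenic") -> int:
    """Pairwise distance in bp.

    intergenic: bp strictly between the genes (0 when they touch or
    overlap); start_to_start: absolute difference of start coordinates.
    """
    if a.scaffold_id != b.scaffold_id:
        raise ValueError(
            f"genes {a.gene_id}/{b.gene_id} are on different scaffolds"
        )
    if mode == "start_to_start":
        return abs(a.start - b.start)
    upstream, downstream = (a, b) if a.start <= b.start else (b, a)
    return max(0, downstream.start - upstream.end - 1)


def detect_tandem_clusters(
    genes: Sequence[GeneRecord],
    groups: GroupSet,
    params: TandemParams | None = None,
) -> list[TandemCluster]:
    """Detect tandem duplicated gene clusters.

    Within each (group, scaffold) restriction every gene pair satisfying
    the intervening-gene and distance criteria is linked; connected
    components of the links with >= ``min_members`` genes are emitted,
    sorted by (scaffold, start of first member).  Grouped genes missing
    from the catalog produce a warning and are skipped.
    """
    params = params or TandemParams()
    by_id = {g.gene_id: g for g in genes}
    if any(g.rank < 0 for g in genes):
        raise ValueError("ranks not assigned; call assign_gene_order first")

    clusters: list[TandemCluster] = []
    for group_id in groups.groups:
        members: list[GeneRecord] = []
        for gene_id in groups.members(group_id):
            rec = by_id.get(gene_id)
            if rec is None:
                warnings.warn(
                    f"group {group_id}: gene {gene_id!r} absent from catalog, skipped",
                    stacklevel=2,
                )
                continue
            members.append(rec)
        by_scaffold: dict[str, list[GeneRecord]] = {}
        for rec in members:
            by_scaffold.setdefault(rec.scaffold_id, []).append(rec)
        for scaffold_id, scaff_members in by_scaffold.items():
            if len(scaff_members) < 2:
                continue
            scaff_members.sort(key=lambda g: (g.start, g.end, g.gene_id))
            link = nx.Graph()
            link.add_nodes_from(g.gene_id for g in scaff_members)
            for i in range(len(scaff_members)):
                for j in range(i + 1, len(scaff_members)):
                    a, b = scaff_members[i], scaff_members[j]
                    if intervening_count(a, b) > params.max_intervening:
                        continue
                    if gene_distance(a, b, params.distance_mode) >= params.max_distance:
                        continue
                    link.add_edge(a.gene_id, b.gene_id)
            for comp in nx.connected_components(link):
                if len(comp) < params.min_members:
                    continue
                comp_recs = sorted(
                    (by_id[g] for g in comp), key=lambda g: (g.start, g.end, g.gene_id)
                )
                clusters.append(
                    TandemCluster(
                        cluster_id="",  # assigned after global sort
                        group_id=group_id,
                        scaffold_id=scaffold_id,
                        member_gene_ids=[g.gene_id for g in comp_recs],
                        span_bp=comp_recs[-1].end - comp_recs[0].start + 1,
                    )
                )
    clusters.sort(key=lambda c: (c.scaffold_id, by_id[c.member_gene_ids[0]].start, c.group_id))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"TD{i:06d}"
    return clusters


def tandem_summary(
    clusters: Iterable[TandemCluster],
) -> tuple[int, int, dict[int, int]]:
    """(n_clusters, n_genes, histogram of cluster sizes)."""
    n_clusters = 0
    n_genes = 0
    hist: dict[int, int] = {}
    for c in clusters:
        n_clusters += 1
        n_genes += c.size
        hist[c.size] = hist.get(c.size, 0) + 1
    return n_clusters, n_genes, hist


def write_clusters_tsv(clusters: Iterable[TandemCluster], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# cluster_id\tgroup_id\tscaffold\tn_members\tspan_bp\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.group_id}\t{c.scaffold_id}\t{c.size}\t{c.span_bp}\t"
                + ",".join(c.member_gene_ids)
                + "\n"
            )
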