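"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention); all
distance arithmetic in the package is documented in those units.
"""

from __future__ import annotations

from dataclasses import dataclass, field


RANK_UNASSIGNED = -1


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence (scaffold or protein)."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    """One annotated gene.

    ``rank`` is the 0-based order index of the gene on its scaffold after
    sorting by (start, end, gene_id); it is ``RANK_UNASSIGNED`` until
    :func:`tandemgenes.tandem.assign_gene_order` runs.
    """

    gene_id: str
    scaffold_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "."
    rank: int = RANK_UNASSIGNED
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GroupSet:
    """Named paralogous/orthologous groups.

    ``groups`` maps group id to an ordered list of (species_tag, gene_id)
    pairs.  A gene id may appear in at most one group.
    """

    groups: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    species_universe: list[str] = field(default_factory=list)

    def members(self, group_id: str) -> list[str]:
        """Gene ids of one group, file order preserved."""
        return [g for _, g in self.groups[group_id]]

    def group_of(self) -> dict[str, str]:
        """Map gene id -> group id over all groups."""
        out: dict[str, str] = {}
        for gid, members in self.groups.items():
            for _, gene in members:
                out[gene] = gid
        return out

    def species_of_group(self, group_id: str) -> set[str]:
        return {sp for sp, _ in self.groups[group_id]}

    def all_genes(self) -> set[str]:
        return {g for members in self.groups.values() for _, g in members}

    def add(self, group_id: str, members: list[tuple[str, str]]) -> None:
        if group_id in self.groups:
            raise ValueError(f"duplicate group id {group_id!r}")
        seen = self.all_genes()
        for _, gene in members:
            if gene in seen:
                raise ValueError(f"gene {gene!r} already assigned to a group")
        if not members:
            raise ValueError(f"group {group_id!r} has no members")
        self.groups[group_id] = list(members)
        for sp, _ in members:
            if sp not in self.species_universe:
                self.species_universe.append(sp)

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class SimilarityHit:
    """One pairwise protein alignment record (12-column tabular dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0,100]")
        if self.aln_length < 1:
            raise ValueError(f"aln_length {self.aln_length} < 1")
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} < 0")


@dataclass
class GoMap:
    """Gene -> set of functional category labels (opaque strings)."""

    annotations: dict[str, set[str]] = field(default_factory=dict)

    def add(self, gene_id: str, category: str) -> None:
        if not gene_id:
            raise ValueError("blank gene id in GO map")
        if not category:
            raise ValueError("empty category label in GO map")
        self.annotations.setdefault(gene_id, set()).add(category)

    def categories(self) -> set[str]:
        return {c for cats in self.annotations.values() for c in cats}

    def genes_with(self, category: str) -> set[str]:
        return {g for g, cats in self.annotations.items() if category in cats}
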