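"""Multi-species orthogroup partitioning (Venn counts) and singleton
accounting.

Each orthogroup contributes one count to the signature of the exact
species subset it contains; marginal queries (all groups containing a
species) sum over signatures.  A singleton is a gene assigned to no
orthogroup (the "unassigned" semantics of common orthology tools); an
alternative definition — a single-member group — is available via
``single_member_groups``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import GroupSet


@dataclass
class VennPartition:
    counts: dict[frozenset[str], int] = field(default_factory=dict)
    species_universe: list[str] = field(default_factory=list)
    singletons: dict[str, int] = field(default_factory=dict)

    def marginal(self, species: str) -> int:
        """Number of groups containing at least one gene of a species."""
        return sum(n for sig, n in self.counts.items() if species in sig)

    def core(self) -> int:
        """Groups containing every species in the universe."""
        return self.counts.get(frozenset(self.species_universe), 0)

    def total_groups(self) -> int:
        return sum(self.counts.values())


def species_signature(groups: GroupSet) -> VennPartition:
    """Tally orthogroups by their exact species-presence subset."""
    counts: dict[frozenset[str], int] = {}
    for gid, members in groups.groups.items():
        for sp, gene in members:
            if not sp:
                raise ValueError(f"group {gid}: member {gene!r} has no species tag")
        sig = frozenset(sp for sp, _ in members)
        counts[sig] = counts.get(sig, 0) + 1
    return VennPartition(counts=counts, species_universe=list(groups.species_universe))


def count_singletons(
    all_genes_by_species: Mapping[str, Sequence[str]], groups: GroupSet
) -> dict[str, int]:
    """Per species, genes appearing in no group of the GroupSet."""
    grouped_by_species: dict[str, set[str]] = {}
    for members in groups.groups.values():
        for sp, gene in members:
            grouped_by_species.setdefault(sp, set()).add(gene)
    import warnings

    out: dict[str, int] = {}
    for sp, inventory in all_genes_by_species.items():
        inv = set(inventory)
        grouped = grouped_by_species.get(sp, set())
        missing = grouped - inv
        if missing:
            warnings.warn(
                f"species {sp}: {len(missing)} grouped gene(s) missing from inventory",
                stacklevel=2,
            )
        out[sp] = len(inv - grouped)
    return out


def single_member_groups(groups: GroupSet) -> int:
    """Alternative singleton notion: groups of size 1."""
    return sum(1 for members in groups.groups.values() if len(members) == 1)


def write_venn_tsv(partition: VennPartition, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# species_subset\tn_groups\n")
        for sig in sorted(partition.counts, key=lambda s: (len(s), sorted(s))):
            fh.write("+".join(sorted(sig)) + f"\t{partition.counts[sig]}\n")
        for sp in sorted(partition.singletons):
            fh.write(f"# singletons {sp}\t{partition.singletons[sp]}\n")
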