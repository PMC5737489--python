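"""Candidate pathway-gene identification and physical-neighborhood scans.

Candidates for pathway enzymes are found by the top-hit rule: for each
reference enzyme (e.g. a characterized protein from a related species),
keep the single alignment with the highest bitscore and report its
percent identity and reference-relative coverage.  A separate scan then
looks for physical clustering — candidate genes from one or more
pathway stages lying close together on one scaffold, the classic
signature of a biosynthetic gene cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import GeneRecord, SimilarityHit
from .tandem import gene_distance


@dataclass
class ReferenceEnzyme:
    ref_id: str  # accession
    enzyme_abbr: str  # e.g. DXR
    pathway_stage: str  # e.g. MEP / iridoid / alkaloid
    protein_length: int  # residues

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError(f"{self.ref_id}: protein_length must be >= 1")


@dataclass
class CandidateHit:
    ref: ReferenceEnzyme
    gene_id: str | None  # None when the reference had no hits
    pct_coverage: float | None  # % of reference length aligned, capped at 100
    pct_identity: float | None
    bitscore: float | None


@dataclass
class PathwayNeighborhood:
    scaffold_id: str
    first_start: int
    last_end: int
    members: list[tuple[str, str, str]]  # (gene_id, enzyme_abbr, stage), by start
    n_stages: int

    @property
    def span_bp(self) -> int:
        return self.last_end - self.first_start + 1


def best_hits(
    hits: Sequence[SimilarityHit], refs: Sequence[ReferenceEnzyme]
) -> list[CandidateHit]:
    """Per reference, the single hit with max bitscore (ties: higher
    identity, then lexicographic gene id).  Coverage is
    100 * aln_length / reference protein length, capped at 100.
    References without hits are reported with an empty candidate."""
    by_query: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: list[CandidateHit] = []
    for ref in refs:
        candidates = by_query.get(ref.ref_id, [])
        if not candidates:
            out.append(CandidateHit(ref=ref, gene_id=None, pct_coverage=None,
                                    pct_identity=None, bitscore=None))
            continue
        best = min(
            candidates,
            key=lambda h: (-h.bitscore, -h.pct_identity, h.subject_id),
        )
        coverage = min(100.0, 100.0 * best.aln_length / ref.protein_length)
        out.append(
            CandidateHit(
                ref=ref,
                gene_id=best.subject_id,
                pct_coverage=coverage,
                pct_identity=best.pct_identity,
                bitscore=best.bitscore,
            )
        )
    return out


def find_neighborhoods(
    genes: Sequence[GeneRecord],
    candidates: Mapping[str, tuple[str, str]],  # gene_id -> (enzyme_abbr, stage)
    max_gap: int = 100_000,
    min_members: int = 2,
    min_stages: int = 2,
) -> list[PathwayNeighborhood]:
    """Chain candidate genes along each scaffold.

    Successive candidates whose intergenic distance is <= ``max_gap``
    join one chain; maximal chains with >= ``min_members`` members and
    >= ``min_stages`` distinct pathway stages are emitted, sorted by
    (scaffold, start)."""
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    by_id = {g.gene_id: g for g in genes}
    for gene_id in candidates:
        if gene_id not in by_id:
            warnings.warn(f"candidate gene {gene_id!r} absent from catalog, skipped",
                          stacklevel=2)
    placed = [by_id[g] for g in candidates if g in by_id]
    by_scaffold: dict[str, list[GeneRecord]] = {}
    for rec in placed:
        by_scaffold.setdefault(rec.scaffold_id, []).append(rec)

    out: list[PathwayNeighborhood] = []
    for scaffold_id in sorted(by_scaffold):
        chain: list[GeneRecord] = []
        ordered = sorted(by_scaffold[scaffold_id], key=lambda g: (g.start, g.end, g.gene_id))
        for rec in ordered:
            if chain and gene_distance(chain[-1], rec) > max_gap:
                _emit(chain, candidates, min_members, min_stages, out)
                chain = []
            chain.append(rec)
        _emit(chain, candidates, min_members, min_stages, out)
    out.sort(key=lambda n: (n.scaffold_id, n.first_start))
    return out


def _emit(
    chain: list[GeneRecord],
    candidates: Mapping[str, tuple[str, str]],
    min_members: int,
    min_stages: int,
    out: list[PathwayNeighborhood],
) -> None:
    if len(chain) < min_members:
        return
    stages = {candidates[g.gene_id][1] for g in chain}
    if len(stages) < min_stages:
        return
    out.append(
        PathwayNeighborhood(
            scaffold_id=chain[0].scaffold_id,
            first_start=chain[0].start,
            last_end=max(g.end for g in chain),
            members=[(g.gene_id, *candidates[g.gene_id]) for g in chain],
            n_stages=len(stages),
        )
    )


# ------------------------------------------------------------- I/O


def read_reference_list(path: str) -> list[ReferenceEnzyme]:
    """TSV: ref_id, enzyme_abbr, pathway_stage, protein_length."""
    refs: list[ReferenceEnzyme] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            refs.append(
                ReferenceEnzyme(
                    ref_id=cols[0],
                    enzyme_abbr=cols[1],
                    pathway_stage=cols[2],
                    protein_length=int(cols[3]),
                )
            )
    return refs


def write_candidates_tsv(candidates: Iterable[CandidateHit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# ref_id\tenzyme\tstage\tgene_id\tpct_coverage\tpct_identity\tbitscore\n")
        for c in candidates:
            if c.gene_id is None:
                fh.write(f"{c.ref.ref_id}\t{c.ref.enzyme_abbr}\t{c.ref.pathway_stage}\tNA\tNA\tNA\tNA\n")
            else:
                fh.write(
                    f"{c.ref.ref_id}\t{c.ref.enzyme_abbr}\t{c.ref.pathway_stage}\t"
                    f"{c.gene_id}\t{c.pct_coverage:.0f}\t{c.pct_identity:.2f}\t{c.bitscore:.1f}\n"
                )


def write_neighborhoods_tsv(neighborhoods: Iterable[PathwayNeighborhood], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# scaffold\tfirst_start\tlast_end\tspan_bp\tn_stages\tmembers\n")
        for n in neighborhoods:
            members = ",".join(f"{g}:{abbr}:{stage}" for g, abbr, stage in n.members)
            fh.write(
                f"{n.scaffold_id}\t{n.first_start}\t{n.last_end}\t{n.span_bp}\t{n.n_stages}\t{members}\n"
            )
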