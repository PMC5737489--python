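"""Readers and writers for the external file formats the pipeline touches.

Supported dialects: FASTA, GFF3 gene rows, OrthoFinder-style
``Orthogroups.txt`` (one ``OG: member member ...`` line per group),
12-column tabular protein-similarity tables, and a 2-column gene/GO TSV.
All TSV outputs start with a commented ``#`` header line.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .model import GeneRecord, GoMap, GroupSet, SequenceRecord, SimilarityHit


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and the description after the first
    whitespace is dropped from the id.  Duplicate ids are a hard error;
    an empty file yields an empty list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ----------------------------------------------------------------- GFF3


def _parse_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Read gene rows from a GFF3 file.

    One :class:`GeneRecord` per row of ``feature_type``; mRNA/exon/CDS
    rows are ignored.  Coordinates stay 1-based inclusive.  Rows with
    start > end or without an ID attribute are hard errors carrying the
    line number.  Ranks are left unassigned.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            if cols[2] != feature_type:
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            attrs = _parse_attributes(cols[8])
            if "ID" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
            gene_id = attrs["ID"]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            strand = cols[6] if cols[6] in {"+", "-", "."} else "."
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    scaffold_id=cols[0],
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return records


def write_gff3(genes: Iterable[GeneRecord], path: str | Path, source: str = "tandemgenes") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ----------------------------------------------------- Orthogroups.txt


def read_orthogroups(
    path: str | Path,
    species_from_prefix: bool = False,
    default_species: str = "sp",
) -> GroupSet:
    """Parse the colon-separated one-line-per-group orthogroup dialect.

    Each line looks like ``OG0000001: geneA geneB``.  When
    ``species_from_prefix`` is true, members of the form ``species|gene``
    carry their species tag; otherwise every member gets
    ``default_species``.  A gene listed in two groups is a hard error.
    """
    gs = GroupSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise FormatError(f"{path}:{lineno}: missing ':' separator")
            gid, rest = line.split(":", 1)
            gid = gid.strip()
            if not gid:
                raise FormatError(f"{path}:{lineno}: empty group id")
            names = rest.split()
            if not names:
                raise FormatError(f"{path}:{lineno}: group {gid!r} has no members")
            members: list[tuple[str, str]] = []
            for name in names:
                if species_from_prefix and "|" in name:
                    sp, gene = name.split("|", 1)
                else:
                    sp, gene = default_species, name
                members.append((sp, gene))
            try:
                gs.add(gid, members)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return gs


def write_orthogroups(groups: GroupSet, path: str | Path, with_species_prefix: bool = False) -> None:
    with open(path, "w") as fh:
        for gid, members in groups.groups.items():
            if with_species_prefix:
                names = [f"{sp}|{gene}" for sp, gene in members]
            else:
                names = [gene for _, gene in members]
            fh.write(f"{gid}: {' '.join(names)}\n")


# ------------------------------------------------- similarity table


def read_similarity_table(path: str | Path) -> list[SimilarityHit]:
    """Read a tab-separated 12-column alignment table.

    Row order is preserved and self-hits are retained (downstream steps
    filter them).  A row with the wrong column count is a hard error.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                hits.append(
                    SimilarityHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        aln_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        qstart=int(cols[6]),
                        qend=int(cols[7]),
                        sstart=int(cols[8]),
                        send=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_similarity_table(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.qstart,
                        h.qend,
                        h.sstart,
                        h.send,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ------------------------------------------------------------- GO map


def read_go_map(path: str | Path) -> GoMap:
    """Read a 2-column TSV of (gene id, category); duplicates collapse."""
    go = GoMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            gene, cat = cols
            if not gene.strip():
                raise FormatError(f"{path}:{lineno}: blank gene id")
            try:
                go.add(gene.strip(), cat.strip())
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return go


def write_go_map(go: GoMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tcategory\n")
        for gene in sorted(go.annotations):
            for cat in sorted(go.annotations[gene]):
                fh.write(f"{gene}\t{cat}\n")
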