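"""Assembly summary metrics and pre-release scaffold filtering.

Computes the usual release-table numbers: total length, scaffold count,
extremes, scaffold and contig N50, N counts and gap (N-run) counts.  A
"gap" is a maximal run of at least ``min_gap_len`` Ns (default 10, a
common scaffolding convention); the same threshold splits scaffolds into
contigs for the contig N50.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .model import SequenceRecord

DEFAULT_MIN_GAP_LEN = 10

_N_RUN = re.compile(r"N+")


@dataclass
class AssemblyMetrics:
    total_length: int
    n_scaffolds: int
    max_len: int
    min_len: int
    n50_scaffold: int
    n50_contig: int
    n_count: int
    n_percent: float  # one decimal, half-away-from-zero
    n_gaps: int


@dataclass
class FilterReport:
    """One row per removed scaffold with the reason for removal."""

    removed: list[tuple[str, int, str]]  # (id, length, reason)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, reason in self.removed:
            out[reason] = out.get(reason, 0) + 1
        return out


def n50(lengths: Sequence[int]) -> int:
    """N50: in descending order, the first length whose running sum
    reaches at least half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def split_contigs(seq: str, min_gap_len: int = DEFAULT_MIN_GAP_LEN) -> list[int]:
    """Lengths of maximal substrings free of N runs >= ``min_gap_len``.

    Shorter N runs stay inside contigs; an all-N sequence yields an
    empty list.
    """
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    pattern = re.compile("N{%d,}" % min_gap_len)
    return [len(part) for part in pattern.split(seq.upper()) if part]


def count_gap_runs(seq: str, min_gap_len: int = DEFAULT_MIN_GAP_LEN) -> int:
    """Number of maximal N runs of length >= ``min_gap_len``."""
    return sum(1 for m in _N_RUN.finditer(seq.upper()) if len(m.group()) >= min_gap_len)


def percent_one_decimal(part: int, whole: int) -> float:
    """Percentage rounded half-away-from-zero to one decimal place."""
    if whole == 0:
        raise ValueError("zero denominator")
    pct = Decimal(part) * 100 / Decimal(whole)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def assembly_metrics(
    records: Sequence[SequenceRecord], min_gap_len: int = DEFAULT_MIN_GAP_LEN
) -> AssemblyMetrics:
    if not records:
        raise ValueError("assembly_metrics needs at least one record")
    lengths = [len(r) for r in records]
    total = sum(lengths)
    contig_lengths: list[int] = []
    n_count = 0
    gaps = 0
    for rec in records:
        seq = rec.sequence.upper()
        n_count += seq.count("N")
        contig_lengths.extend(split_contigs(seq, min_gap_len))
        gaps += count_gap_runs(seq, min_gap_len)
    return AssemblyMetrics(
        total_length=total,
        n_scaffolds=len(records),
        max_len=max(lengths),
        min_len=min(lengths),
        n50_scaffold=n50(lengths),
        n50_contig=n50(contig_lengths) if contig_lengths else 0,
        n_count=n_count,
        n_percent=percent_one_decimal(n_count, total),
        n_gaps=gaps,
    )


def filter_scaffolds(
    records: Iterable[SequenceRecord],
    min_length: int = 0,
    exclude_ids: set[str] | None = None,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Drop scaffolds shorter than ``min_length`` or listed in
    ``exclude_ids`` (e.g. flagged contaminants); survivor order is
    preserved and every removal is reported with its reason."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    exclude_ids = set(exclude_ids or ())
    kept: list[SequenceRecord] = []
    removed: list[tuple[str, int, str]] = []
    seen_ids = set()
    for rec in records:
        seen_ids.add(rec.id)
        if rec.id in exclude_ids:
            removed.append((rec.id, len(rec), "excluded_id"))
        elif len(rec) < min_length:
            removed.append((rec.id, len(rec), "below_min_length"))
        else:
            kept.append(rec)
    for missing in exclude_ids - seen_ids:
        warnings.warn(f"exclude id {missing!r} not present in assembly", stacklevel=2)
    return kept, FilterReport(removed=removed)


def write_metrics_tsv(metrics: AssemblyMetrics, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# metric\tvalue\n")
        fh.write(f"total_length\t{metrics.total_length}\n")
        fh.write(f"n_scaffolds\t{metrics.n_scaffolds}\n")
        fh.write(f"max_len\t{metrics.max_len}\n")
        fh.write(f"min_len\t{metrics.min_len}\n")
        fh.write(f"n50_scaffold\t{metrics.n50_scaffold}\n")
        fh.write(f"n50_contig\t{metrics.n50_contig}\n")
        fh.write(f"n_count\t{metrics.n_count}\n")
        fh.write(f"n_percent\t{metrics.n_percent}\n")
        fh.write(f"n_gaps\t{metrics.n_gaps}\n")
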