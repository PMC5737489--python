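"""Synthetic genome annotations with planted truth.

Generates a small genome — scaffolds carrying non-overlapping genes
placed left-to-right with sampled intergenic gaps — together with every
derived file the pipeline consumes: proteins, a paralog-group file, a
pairwise-similarity table, and a gene/GO map.  The generator plants

* tandem arrays: whole paralog families laid out as consecutive genes
  on one scaffold with spacing well below the tandem distance bound;
* dispersed families: paralogs on different scaffolds (or, when there
  are more members than scaffolds, far enough apart on one scaffold
  that no tandem criterion can link them);
* a GO category enriched among tandem-array genes at a controlled odds
  ratio;
* intergenic N runs (assembly gaps), never inside genes.

All sampling is routed through one numpy Generator seeded from a single
integer, so identical parameters produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import GeneRecord, GoMap, GroupSet, SequenceRecord, SimilarityHit
from . import formats

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_N_BYTE = ord("N")

DEFAULT_GO_TERMS = [
    "response to stress",
    "transport",
    "other cellular processes",
    "cell organization and biogenesis",
    "other metabolic processes",
    "unknown biological processes",
]


@dataclass
class SimParams:
    seed: int = 0
    n_scaffolds: int = 10
    genes_per_scaffold: tuple[int, int] = (150, 250)
    gene_length: tuple[int, int] = (1_000, 5_000)  # bp
    intergenic_gap: tuple[int, int] = (2_000, 20_000)  # bp
    n_families: int = 60
    family_size: tuple[int, int] = (2, 6)
    tandem_fraction: float = 0.5
    array_spacing: tuple[int, int] = (200, 5_000)  # bp, below the 100 kbp bound
    dispersed_min_separation: int = 200_000  # bp
    within_family_identity: float = 90.0  # percent
    go_terms: list[str] = field(default_factory=lambda: list(DEFAULT_GO_TERMS))
    enriched_term_odds_ratio: float = 4.0
    baseline_term_prob: float = 0.10  # p0 for the designated term
    other_term_prob: float = 0.10
    gap_runs_per_scaffold: tuple[int, int] = (0, 3)
    gap_run_length: tuple[int, int] = (10, 500)
    protein_length: tuple[int, int] = (200, 500)  # residues
    noise_hits: int = 0
    noise_evalue: float = 1e-3

    def __post_init__(self) -> None:
        for name in (
            "genes_per_scaffold", "gene_length", "intergenic_gap", "family_size",
            "array_spacing", "gap_runs_per_scaffold", "gap_run_length", "protein_length",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name}: empty or negative range ({lo}, {hi})")
        if not 0 <= self.tandem_fraction <= 1:
            raise ValueError("tandem_fraction must be in [0, 1]")
        if self.array_spacing[1] >= 100_000:
            raise ValueError("array_spacing must stay below the 100 kbp tandem bound")


@dataclass
class TruthTables:
    """Planted ground truth, consistent with the emitted files."""

    genes: list[GeneRecord] = field(default_factory=list)
    families: dict[str, list[str]] = field(default_factory=dict)  # family -> gene ids
    tandem_arrays: list[tuple[str, str, list[str]]] = field(default_factory=list)
    # (family_id, scaffold_id, member gene ids in coordinate order)
    go: dict[str, set[str]] = field(default_factory=dict)  # gene -> terms
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    # scaffold -> [(start, end)] 1-based inclusive N runs
    hit_identities: dict[tuple[str, str], float] = field(default_factory=dict)
    protein_lengths: dict[str, int] = field(default_factory=dict)

    def tandem_gene_ids(self) -> set[str]:
        return {g for _, _, members in self.tandem_arrays for g in members}


def _randint(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def simulate_annotation(
    params: SimParams,
) -> tuple[list[SequenceRecord], list[GeneRecord], TruthTables]:
    """Build scaffolds, gene coordinates, families, and planted truth.

    Raises a sizing error when the requested families cannot be placed
    on the requested scaffolds.
    """
    rng = np.random.default_rng(params.seed)
    truth = TruthTables()

    n_genes_per_scaffold = [
        _randint(rng, params.genes_per_scaffold) for _ in range(params.n_scaffolds)
    ]
    scaffold_ids = [f"scaffold_{i + 1}" for i in range(params.n_scaffolds)]
    # slot[s][j] = family id or None; tandem runs reserved first
    slots: list[list[str | None]] = [[None] * n for n in n_genes_per_scaffold]

    sizes = [_randint(rng, params.family_size) for _ in range(params.n_families)]
    n_tandem = round(params.tandem_fraction * params.n_families)
    tandem_ids = [f"FAM{i + 1:04d}" for i in range(n_tandem)]
    dispersed_ids = [f"FAM{i + 1:04d}" for i in range(n_tandem, params.n_families)]

    # --- tandem arrays: a run of k consecutive free slots on one scaffold
    for fam, size in zip(tandem_ids, sizes[:n_tandem]):
        placed = False
        for s in rng.permutation(params.n_scaffolds):
            free_starts = [
                j
                for j in range(len(slots[s]) - size + 1)
                if all(slots[s][j + t] is None for t in range(size))
            ]
            if free_starts:
                j = free_starts[int(rng.integers(len(free_starts)))]
                for t in range(size):
                    slots[s][j + t] = fam
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot place tandem family {fam} of size {size}: "
                "increase genes_per_scaffold or n_scaffolds"
            )

    # --- dispersed families: distinct scaffolds preferred; same-scaffold
    # members forced far enough apart in slot space that even minimal
    # gene/gap sizes keep them >= dispersed_min_separation bp apart
    min_unit = params.gene_length[0] + min(params.intergenic_gap[0], params.array_spacing[0])
    sep_slots = math.ceil(params.dispersed_min_separation / max(1, min_unit)) + 1
    for fam, size in zip(dispersed_ids, sizes[n_tandem:]):
        taken: dict[int, list[int]] = {}  # scaffold -> slot indices used by this family
        for _ in range(size):
            placed = False
            for s in rng.permutation(params.n_scaffolds):
                if s in taken and params.n_scaffolds >= size:
                    continue  # prefer cross-scaffold placement
                free = [
                    j
                    for j in range(len(slots[s]))
                    if slots[s][j] is None
                    and all(abs(j - j0) >= sep_slots for j0 in taken.get(s, []))
                ]
                if free:
                    j = free[int(rng.integers(len(free)))]
                    slots[s][j] = fam
                    taken.setdefault(s, []).append(j)
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"cannot place dispersed family {fam} of size {size} with "
                    f"separation {params.dispersed_min_separation} bp: increase "
                    "scaffold gene counts or n_scaffolds"
                )

    # --- coordinates, left to right; array-internal gaps use array_spacing
    fam_members: dict[str, list[str]] = {f: [] for f in tandem_ids + dispersed_ids}
    gene_counter = 0
    scaffold_seq_len: dict[str, int] = {}
    for s, scaffold_id in enumerate(scaffold_ids):
        pos = 0  # last occupied bp (0 = nothing yet)
        prev_fam: str | None = None
        prev_was_array = False
        for j, fam in enumerate(slots[s]):
            in_array_run = (
                fam is not None
                and fam in fam_members
                and fam == prev_fam
                and prev_was_array
            )
            gap = _randint(
                rng, params.array_spacing if in_array_run else params.intergenic_gap
            )
            start = pos + gap + 1
            length = _randint(rng, params.gene_length)
            end = start + length - 1
            gene_counter += 1
            gene_id = f"gene_{gene_counter:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            truth.genes.append(
                GeneRecord(gene_id=gene_id, scaffold_id=scaffold_id,
                           start=start, end=end, strand=strand)
            )
            if fam is not None:
                fam_members[fam].append(gene_id)
            pos = end
            prev_fam = fam
            prev_was_array = fam in tandem_ids if fam is not None else False
        scaffold_seq_len[scaffold_id] = pos + _randint(rng, params.intergenic_gap)

    from .tandem import assign_gene_order

    assign_gene_order(truth.genes)
    truth.families = {f: m for f, m in fam_members.items() if m}
    by_id = {g.gene_id: g for g in truth.genes}
    for fam in tandem_ids:
        members = fam_members[fam]
        if members:
            scaffold = by_id[members[0]].scaffold_id
            ordered = sorted(members, key=lambda g: by_id[g].start)
            truth.tandem_arrays.append((fam, scaffold, ordered))

    # --- scaffold sequences with intergenic N runs
    scaffolds: list[SequenceRecord] = []
    genes_by_scaffold: dict[str, list[GeneRecord]] = {}
    for g in truth.genes:
        genes_by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for scaffold_id in scaffold_ids:
        length = scaffold_seq_len[scaffold_id]
        seq = _NT[rng.integers(0, 4, size=length)]
        placed_runs: list[tuple[int, int]] = []
        n_runs = _randint(rng, params.gap_runs_per_scaffold)
        ordered = sorted(genes_by_scaffold.get(scaffold_id, []), key=lambda g: g.start)
        # intergenic intervals (1-based, exclusive of gene bp), with 1 bp margin
        intervals = []
        prev_end = 0
        for g in ordered:
            if g.start - prev_end - 1 > 2:
                intervals.append((prev_end + 2, g.start - 2))
            prev_end = g.end
        if length - prev_end - 1 > 2:
            intervals.append((prev_end + 2, length - 1))
        free = list(intervals)
        for _ in range(n_runs):
            run_len = _randint(rng, params.gap_run_length)
            fits = [iv for iv in free if iv[1] - iv[0] + 1 >= run_len]
            if not fits:
                continue
            lo, hi = fits[int(rng.integers(len(fits)))]
            start = int(rng.integers(lo, hi - run_len + 2))
            seq[start - 1 : start - 1 + run_len] = _N_BYTE
            placed_runs.append((start, start + run_len - 1))
            free.remove((lo, hi))  # one run per interval so runs never merge
        placed_runs.sort()
        truth.gaps[scaffold_id] = placed_runs
        scaffolds.append(SequenceRecord(id=scaffold_id, sequence=seq.tobytes().decode()))

    return scaffolds, truth.genes, truth


def truth_groupset(truth: TruthTables, species: str = "sp") -> GroupSet:
    """Planted families as a GroupSet (>= 2 members only)."""
    gs = GroupSet()
    for i, (fam, members) in enumerate(sorted(truth.families.items()), start=1):
        if len(members) >= 2:
            gs.add(f"OG{i:06d}", [(species, g) for g in members])
    return gs


def simulate_proteins(
    truth: TruthTables, params: SimParams
) -> list[SequenceRecord]:
    """One ancestral random protein per family; members diverge by point
    substitution so the expected pairwise identity equals
    ``within_family_identity``.  Non-family genes are independent."""
    rng = np.random.default_rng(params.seed + 1)
    target = params.within_family_identity / 100.0
    # per-member substitution rate r: pairwise match = (1-r)^2 + r^2/19
    # solve ((1-r)^2 + r^2/19) = target for r in [0, 1]
    a, b, c = 1 + 1 / 19, -2.0, 1 - target
    r = (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)
    proteins: list[SequenceRecord] = []
    family_of = {g: f for f, members in truth.families.items() for g in members}
    # ancestors as residue indices 0..19 so substitution is an index shift
    ancestors: dict[str, np.ndarray] = {}
    for fam in sorted(truth.families):
        ancestors[fam] = rng.integers(0, 20, size=_randint(rng, params.protein_length))
    for g in truth.genes:
        fam = family_of.get(g.gene_id)
        if fam is None:
            idx = rng.integers(0, 20, size=_randint(rng, params.protein_length))
        else:
            idx = ancestors[fam].copy()
            mask = rng.random(len(idx)) < r
            # shift by 1..19 mod 20: uniform over the 19 other residues
            idx[mask] = (idx[mask] + rng.integers(1, 20, size=int(mask.sum()))) % 20
        proteins.append(
            SequenceRecord(id=g.gene_id, sequence=_AA[idx].tobytes().decode())
        )
        truth.protein_lengths[g.gene_id] = len(idx)
    return proteins


def _pct_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / n


def simulate_similarity(
    truth: TruthTables,
    params: SimParams,
    proteins: list[SequenceRecord] | None = None,
) -> list[SimilarityHit]:
    """Reciprocal within-family hits; optional sub-threshold noise hits
    between families.  Bitscore grows with identity x length and the
    E-value falls with bitscore."""
    rng = np.random.default_rng(params.seed + 2)
    if proteins is None:
        proteins = simulate_proteins(truth, params)
    seq_of = {p.id: p.sequence for p in proteins}
    hits: list[SimilarityHit] = []

    def emit(q: str, s: str, identity: float, evalue: float | None = None) -> None:
        aln = min(len(seq_of[q]), len(seq_of[s]))
        bitscore = round(2.0 * identity / 100.0 * aln, 1)
        if evalue is None:
            evalue = 10.0 ** (-min(180.0, bitscore / 10.0))
        mism = round(aln * (1 - identity / 100.0))
        hits.append(
            SimilarityHit(
                query_id=q, subject_id=s, pct_identity=round(identity, 2),
                aln_length=aln, mismatches=mism, gap_opens=0,
                qstart=1, qend=aln, sstart=1, send=aln,
                evalue=evalue, bitscore=bitscore,
            )
        )

    for fam in sorted(truth.families):
        members = truth.families[fam]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                identity = _pct_identity(seq_of[a], seq_of[b])
                truth.hit_identities[(a, b)] = round(identity, 2)
                emit(a, b, identity)
                emit(b, a, identity)

    fams = sorted(truth.families)
    for _ in range(params.noise_hits):
        if len(fams) < 2:
            break
        fa, fb = rng.choice(len(fams), size=2, replace=False)
        a = truth.families[fams[fa]][0]
        b = truth.families[fams[fb]][0]
        emit(a, b, identity=float(rng.uniform(20, 35)), evalue=params.noise_evalue)
    return hits


def simulate_go(truth: TruthTables, params: SimParams) -> GoMap:
    """Designated first term enriched among tandem-array genes at the
    configured odds ratio; remaining terms assigned uniformly."""
    rng = np.random.default_rng(params.seed + 3)
    go = GoMap()
    if not params.go_terms:
        return go
    designated = params.go_terms[0]
    p0 = params.baseline_term_prob
    if p0 <= 0:
        p1 = 0.0  # zero baseline odds stay zero under any odds ratio
    else:
        odds1 = params.enriched_term_odds_ratio * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
    tandem_genes = truth.tandem_gene_ids()
    for g in truth.genes:
        p = p1 if g.gene_id in tandem_genes else p0
        if rng.random() < p:
            go.add(g.gene_id, designated)
        for term in params.go_terms[1:]:
            if rng.random() < params.other_term_prob:
                go.add(g.gene_id, term)
    truth.go = {g: set(cats) for g, cats in go.annotations.items()}
    return go


def simulate_all(params: SimParams, outdir: str | Path) -> TruthTables:
    """Run every generator and write the full file set to ``outdir``:
    genome.fa, genes.gff3, proteins.fa, orthogroups.txt, hits.tsv,
    go.tsv and truth tables under truth/."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scaffolds, genes, truth = simulate_annotation(params)
    proteins = simulate_proteins(truth, params)
    hits = simulate_similarity(truth, params, proteins)
    go = simulate_go(truth, params)

    formats.write_fasta(scaffolds, outdir / "genome.fa")
    formats.write_gff3(genes, outdir / "genes.gff3")
    formats.write_fasta(proteins, outdir / "proteins.fa")
    formats.write_orthogroups(truth_groupset(truth), outdir / "orthogroups.txt")
    formats.write_similarity_table(hits, outdir / "hits.tsv")
    formats.write_go_map(go, outdir / "go.tsv")

    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    with open(tdir / "tandem_arrays.tsv", "w") as fh:
        fh.write("# family\tscaffold\tmembers\n")
        for fam, scaffold, members in truth.tandem_arrays:
            fh.write(f"{fam}\t{scaffold}\t{','.join(members)}\n")
    with open(tdir / "families.tsv", "w") as fh:
        fh.write("# family\tmembers\n")
        for fam in sorted(truth.families):
            fh.write(f"{fam}\t{','.join(truth.families[fam])}\n")
    with open(tdir / "gaps.tsv", "w") as fh:
        fh.write("# scaffold\tstart\tend\n")
        for scaffold in sorted(truth.gaps):
            for start, end in truth.gaps[scaffold]:
                fh.write(f"{scaffold}\t{start}\t{end}\n")
    return truth
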