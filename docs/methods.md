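# Methods

## Scope and data model

The package analyses an annotated genome given four inputs: scaffold
sequences (FASTA), a gene catalog (GFF3 gene rows; mRNA/exon rows are
ignored because duplication is counted per gene, not per transcript),
paralogous/orthologous group membership (one-line-per-group
`Orthogroups.txt` dialect), and a pairwise protein-similarity table
(12-column tabular alignment format). Coordinates are kept 1-based
inclusive throughout, matching GFF3; all distances below are in those
units. Gene order on a scaffold is the 0-based rank after sorting by
(start, end, gene id); strand never enters any computation.

## Tandem-cluster detection

Two genes are tandem-linked when they share a group, share a scaffold,
have at most `max_intervening` (default 10) annotated genes between
their ranks, and lie closer than `max_distance` (default 100 000 bp,
strict `<`). Clusters are connected components of the link relation
restricted to each (group, scaffold), keeping components with at least
`min_members` (default 2) genes. Choices that the criteria themselves
leave open, and how they were resolved:

* **Distance definition.** "Gene distance" is ambiguous; the default is
  the intergenic gap (`downstream.start − upstream.end − 1`, floored at
  0 for overlapping genes) because it is invariant to gene length. A
  `start_to_start` mode is provided for comparison with tools that use
  anchor coordinates.
* **Bound conventions.** "No more than 10 between" is inclusive (≤ 10);
  "less than 100 kbp" is strict. Both are asserted at their exact
  boundaries in the test suite.
* **Pairwise vs chained.** The criteria are applied to pairs and chained
  transitively: a run of k co-group genes each near its neighbours forms
  one k-gene cluster even when the outermost pair violates the distance
  bound. This matches the observation that reported mean cluster sizes
  exceed 2 and guarantees disjoint clusters (a gene is in at most one
  group, and components partition each group's genes).
* **Intervening genes** are counted over all annotated genes, including
  other members of the same group. Under transitive chaining this is
  harmless: co-group intervening genes are themselves linked.

The detector is validated against an independent brute-force
implementation (all-pairs tests + union-find transitive closure, no
shared code) on randomized instances, and against planted arrays in
simulation.

## Paralog clustering

The similarity graph takes an edge (a, b) when an a→b hit passes the
E-value cutoff (default 1e-5, the conventional screening threshold) and,
in the default reciprocal mode, a b→a hit passes as well; self-hits are
dropped and edge weight is the best supporting bitscore. Paralogous
groups are connected components with ≥ 2 members — a deliberately simple
stand-in for Markov-clustering pipelines that keeps results reproducible
and dependency-light; precomputed orthogroup files from heavier tools
can be supplied everywhere a GroupSet is consumed. Group ids are
assigned by descending size then lexicographic first member, making
output invariant to input order.

`family_partition` splits a labelled gene set (for instance, all
cytochrome P450s) into clusters and singletons with the
restricted-subgroup rule: a group counts as a cluster of the label set
only when it contains ≥ 2 labelled genes, so mixed groups cannot inflate
cluster counts, and labelled genes in no counted cluster are singletons.
The counts always satisfy `cluster_genes + singletons = |label set|`.

## Assembly metrics

N50 is the first length whose cumulative sum, in descending order,
reaches half the total — the standard assembler convention, asserted by
a prefix property test. A gap is a maximal run of ≥ `min_gap_len` Ns
(default 10, a common scaffolding convention; the value is configurable
because annotation pipelines differ), and the same threshold splits
scaffolds into contigs for contig N50. The N percentage is rounded
half-away-from-zero to one decimal, the convention used in release
tables. Scaffold filtering drops sequences below a minimum length or on
an explicit exclusion list (e.g. contaminant matches), reporting each
removal with its reason.

## χ² enrichment

For each category the 2×2 table is (focal with term, focal without,
background with, background without), where the background is the
complement of the focal set within all annotated genes — disjoint
classes, as the independence test requires — and unannotated genes count
as "without term". The statistic is the textbook Pearson χ² with 1 df;
the p-value is the upper tail of the χ² distribution. Yates' continuity
correction is off by default and no multiple-testing correction is
applied by default, matching the common practice of reporting raw
P-values at a stringent α (1e-4); both are available as flags. A table
with a zero marginal is reported as untestable rather than given a
fabricated statistic. Correctness is checked against an independent
implementation (scipy's contingency test) to 1e-9 relative tolerance,
and calibration is checked empirically: the null rejection rate at
α = 0.05 must sit inside binomial 99% bounds over repeated simulated
scans.

## Pathway candidates and neighborhoods

Candidates are chosen per reference enzyme by the top-hit rule: highest
bitscore, ties broken by identity then lexicographic gene id. Coverage
is `100 × aln_length / reference protein length`, capped at 100 —
reference-relative, because the reference enzymes are the characterized
proteins whose span the alignment should cover; this is flagged as an
assumption since tabular alignment output does not record which
convention a published table used. No identity/coverage floor is applied
by default (published candidate tables report top hits down to ~54%
identity); floors are available as flags.

The neighborhood scan generalizes a qualitative observation (homologs of
several pathway stages co-located on one scaffold) into a parameterized
sweep: candidates on a scaffold are chained while successive intergenic
distances stay ≤ `max_gap` (default 100 kbp), and maximal chains with
≥ `min_members` (2) members and ≥ `min_stages` (2) distinct pathway
stages are reported. Defaults are conservative; the scan's maximality is
property-tested.

## Orthogroup partitions

Each group contributes one count to the signature of the exact species
subset present in it; Venn-style marginals are sums over signatures. A
singleton is a gene assigned to no orthogroup (the "unassigned" sense
used by orthology tools); the alternative reading — a one-member group —
is exposed separately (`single_member_groups`) because usage varies.

## The simulator

`simulate_annotation` places non-overlapping genes left-to-right per
scaffold with intergenic gaps sampled uniformly from a range, then
plants paralog families of two kinds: *tandem* families occupy
consecutive slots on one scaffold with spacing sampled from
`array_spacing` (default 200–5000 bp, well below the 100 kbp bound), and
*dispersed* families are placed on distinct scaffolds where possible,
otherwise far enough apart in slot space that even minimal gene/gap
draws keep them ≥ `dispersed_min_separation` (default 200 kbp) apart —
so no tandem criterion can link them, which is what makes the
precision/recall-1.0 recovery checks sharp. Assembly gaps (N runs) are
inserted only into intergenic intervals, at most one per interval and
never flush against a gene, so contig-splitting truth stays trivially
checkable.

Proteins descend from one random ancestral sequence per family; each
member is mutated per site at rate r solved from
`(1−r)² + r²/19 = identity/100`, so the *pairwise* identity between
members matches `within_family_identity` (default 90%) in expectation.
The similarity table contains reciprocal within-family rows whose
identity is measured from the actual sequences, with bitscore
proportional to identity × length and E-value decreasing in bitscore;
optional noise rows between families carry sub-threshold E-values. The
GO map assigns a designated term to tandem-array genes with probability
p1 and to all others with p0 = `baseline_term_prob` (default 0.1), where
the odds ratio p1(1−p0)/(p0(1−p1)) equals `enriched_term_odds_ratio`
(default 4); other terms are assigned uniformly at 0.1.

Default sizes (10 scaffolds × 150–250 genes ≈ 2000 genes, 60 families
of 2–6 members, half laid out as tandem arrays) give desk-scale runs of
well under a second while leaving enough planted structure for the
recovery and calibration checks; the enrichment-power checks use a
larger 15-scaffold ≈ 3000-gene layout with 150 families so the focal set
is ≈ 300 genes. Everything derives from one integer seed through a
single numpy Generator (sub-streams offset deterministically for
proteins, hits and GO), so identical parameters give byte-identical
files.

What the simulator does *not* emulate — realistic nucleotide
composition, intron structure, transposons, alignment noise, GO-graph
structure, partial gene models — bounds what passing tests show: they
validate the algorithms' logic and calibration, not robustness to
annotation artifacts in real genomes.

## Known limitations

* Connected-component paralog clustering is more permissive than MCL at
  low thresholds; on real proteomes supply curated orthogroups instead.
* The χ² test is asymptotic; very sparse categories (expected counts
  < 5) are better served by an exact test, which is intentionally not
  substituted to keep the reported statistic the declared one.
* Criterion semantics (chained-neighbor distance, intergenic measure)
  are documented choices where the original wording is ambiguous;
  results at the margins can differ from tools that chose otherwise.
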