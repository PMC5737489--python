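import random

import pytest

from tandemgenes.model import GeneRecord, GroupSet
from tandemgenes.simulate import SimParams, simulate_annotation, truth_groupset
from tandemgenes.tandem import (
    TandemParams,
    assign_gene_order,
    detect_tandem_clusters,
    gene_distance,
    intervening_count,
    tandem_summary,
)

from conftest import make_genes


# ---------------------------------------------------------------- oracle


def brute_force_clusters(genes, groups, params):
    """Independent all-pairs + transitive-closure reimplementation using
    sorted gene order and union-find; no shared code with the detector."""
    order = {}
    for scaffold in {g.scaffold_id for g in genes}:
        on_s = sorted(
            (g for g in genes if g.scaffold_id == scaffold),
            key=lambda g: (g.start, g.end, g.gene_id),
        )
        for i, g in enumerate(on_s):
            order[g.gene_id] = i
    by_id = {g.gene_id: g for g in genes}

    def dist(a, b):
        if params.distance_mode == "start_to_start":
            return abs(a.start - b.start)
        lo, hi = sorted([a, b], key=lambda g: g.start)
        return max(0, hi.start - lo.end - 1)

    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    out = []
    for gid, members in groups.groups.items():
        present = [by_id[g] for _, g in members if g in by_id]
        for g in present:
            parent[g.gene_id] = g.gene_id
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = present[i], present[j]
                if a.scaffold_id != b.scaffold_id:
                    continue
                if abs(order[a.gene_id] - order[b.gene_id]) - 1 > params.max_intervening:
                    continue
                if dist(a, b) >= params.max_distance:
                    continue
                union(a.gene_id, b.gene_id)
        comps = {}
        for g in present:
            comps.setdefault(find(g.gene_id), []).append(g)
        for comp in comps.values():
            if len(comp) >= params.min_members:
                comp.sort(key=lambda g: (g.start, g.end, g.gene_id))
                out.append((gid, comp[0].scaffold_id, tuple(g.gene_id for g in comp)))
    return set(out)


def random_instance(rng, n_genes=200, n_scaffolds=3, n_groups=12):
    genes = []
    gid = 0
    for s in range(n_scaffolds):
        pos = 1
        for _ in range(n_genes // n_scaffolds):
            start = pos + rng.randrange(100, 40_000)
            end = start + rng.randrange(500, 4_000)
            genes.append(GeneRecord(f"g{gid}", f"sc{s}", start, end))
            gid += 1
            pos = end
    assign_gene_order(genes)
    ids = [g.gene_id for g in genes]
    rng.shuffle(ids)
    groups = GroupSet()
    i = 0
    for k in range(n_groups):
        size = rng.randrange(2, 7)
        members = ids[i : i + size]
        i += size
        if len(members) >= 2:
            groups.add(f"OG{k}", [("sp", m) for m in members])
    return genes, groups


# ----------------------------------------------------------------- tests


class TestGeneOrder:
    def test_ranks_follow_start_order(self):
        genes = [
            GeneRecord("a", "sc1", 100, 200),
            GeneRecord("b", "sc1", 500, 600),
            GeneRecord("c", "sc1", 300, 400),
        ]
        assign_gene_order(genes)
        assert {g.gene_id: g.rank for g in genes} == {"a": 0, "b": 2, "c": 1}

    def test_scaffolds_independent(self):
        genes = [
            GeneRecord("a", "sc1", 100, 200),
            GeneRecord("b", "sc2", 50, 80),
            GeneRecord("c", "sc1", 300, 400),
        ]
        assign_gene_order(genes)
        assert {g.gene_id: g.rank for g in genes} == {"a": 0, "b": 0, "c": 1}

    def test_duplicate_record_is_error(self):
        genes = [GeneRecord("a", "sc1", 1, 9), GeneRecord("a", "sc1", 1, 9)]
        with pytest.raises(ValueError, match="duplicate"):
            assign_gene_order(genes)

    def test_shuffled_genes_recover_truth_ranks(self, small_sim):
        _, _, genes, _ = small_sim
        truth_ranks = {g.gene_id: g.rank for g in genes}
        shuffled = list(genes)
        random.Random(1).shuffle(shuffled)
        assign_gene_order(shuffled)
        assert {g.gene_id: g.rank for g in shuffled} == truth_ranks


class TestPairMeasures:
    def test_intervening_adjacent(self):
        genes = make_genes([100, 2000])
        assert intervening_count(genes[0], genes[1]) == 0

    def test_intervening_counts_all_genes(self):
        genes = make_genes([i * 2000 + 1 for i in range(15)])
        assert intervening_count(genes[2], genes[14]) == 11

    def test_intervening_matches_enumeration(self):
        rng = random.Random(4)
        genes = make_genes(sorted(rng.sample(range(1, 10_000_000, 5000), 60)))
        for _ in range(50):
            a, b = rng.sample(genes, 2)
            between = [
                g for g in genes
                if min(a.start, b.start) < g.start < max(a.start, b.start)
            ]
            assert intervening_count(a, b) == len(between)

    def test_cross_scaffold_is_error(self):
        a = GeneRecord("a", "sc1", 1, 9, rank=0)
        b = GeneRecord("b", "sc2", 1, 9, rank=0)
        with pytest.raises(ValueError):
            intervening_count(a, b)
        with pytest.raises(ValueError):
            gene_distance(a, b)

    def test_intergenic_distance(self):
        a = GeneRecord("a", "sc1", 100, 900)
        b = GeneRecord("b", "sc1", 1000, 1500)
        assert gene_distance(a, b) == 99
        assert gene_distance(b, a) == 99

    def test_overlap_is_zero(self):
        a = GeneRecord("a", "sc1", 100, 900)
        b = GeneRecord("b", "sc1", 800, 1500)
        assert gene_distance(a, b) == 0

    def test_start_to_start(self):
        a = GeneRecord("a", "sc1", 100, 900)
        b = GeneRecord("b", "sc1", 1000, 1500)
        assert gene_distance(a, b, "start_to_start") == 900


def _pair_instance(n_between, intergenic_bp):
    """Two co-group genes separated by n_between filler genes and an
    intergenic distance of intergenic_bp between the flanking pair."""
    length = 100
    starts = [1]
    for _ in range(n_between):
        starts.append(starts[-1] + length + 50)
    starts.append(starts[-1] + length - 1 + intergenic_bp + 1)
    genes = make_genes(starts, length=length)
    groups = GroupSet()
    groups.add("OG1", [("sp", genes[0].gene_id), ("sp", genes[-1].gene_id)])
    return genes, groups


class TestCriteriaBoundaries:
    def test_simple_pair_clusters(self):
        genes, groups = _pair_instance(0, 5_000)
        clusters = detect_tandem_clusters(genes, groups)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_intervening_boundary(self):
        """Exactly 10 intervening genes cluster; 11 do not."""
        genes, groups = _pair_instance(10, 50_000)
        assert len(detect_tandem_clusters(genes, groups)) == 1
        genes, groups = _pair_instance(11, 50_000)
        assert detect_tandem_clusters(genes, groups) == []

    def test_distance_boundary_is_strict(self):
        """99 999 bp clusters; exactly 100 000 bp does not."""
        genes, groups = _pair_instance(0, 99_999)
        assert len(detect_tandem_clusters(genes, groups)) == 1
        genes, groups = _pair_instance(0, 100_000)
        assert detect_tandem_clusters(genes, groups) == []

    def test_cross_scaffold_pair_never_clusters(self):
        genes = make_genes([100], scaffold="sc1") + make_genes([100], scaffold="sc2", prefix="h")
        assign_gene_order(genes)
        groups = GroupSet()
        groups.add("OG1", [("sp", "g0"), ("sp", "h0")])
        assert detect_tandem_clusters(genes, groups) == []


class TestClustering:
    def test_chained_run_is_one_cluster(self):
        """k adjacent pairwise-near co-group genes -> one cluster of k."""
        genes = make_genes([1 + i * 2000 for i in range(5)])
        groups = GroupSet()
        groups.add("OG1", [("sp", g.gene_id) for g in genes])
        clusters = detect_tandem_clusters(genes, groups)
        assert len(clusters) == 1
        assert clusters[0].member_gene_ids == [g.gene_id for g in genes]
        assert clusters[0].span_bp == genes[-1].end - genes[0].start + 1

    def test_disjointness(self, small_sim):
        _, _, genes, truth = small_sim
        clusters = detect_tandem_clusters(genes, truth_groupset(truth))
        seen = set()
        for c in clusters:
            assert not (set(c.member_gene_ids) & seen)
            seen |= set(c.member_gene_ids)

    def test_monotonicity_in_bounds(self):
        """Widening either bound never drops a clustered gene, and every
        narrow-bound cluster is contained in one wide-bound cluster
        (widening refines upward; clusters can merge but not split)."""
        rng = random.Random(9)
        genes, groups = random_instance(rng, n_genes=150)
        base = TandemParams(max_intervening=3, max_distance=30_000)
        wide = TandemParams(max_intervening=10, max_distance=100_000)
        narrow_clusters = detect_tandem_clusters(genes, groups, base)
        wide_clusters = detect_tandem_clusters(genes, groups, wide)
        _, n_g0, _ = tandem_summary(narrow_clusters)
        _, n_g1, _ = tandem_summary(wide_clusters)
        assert n_g1 >= n_g0
        wide_sets = [set(c.member_gene_ids) for c in wide_clusters]
        for c in narrow_clusters:
            assert any(set(c.member_gene_ids) <= w for w in wide_sets)

    def test_missing_gene_warns_and_skips(self):
        genes = make_genes([100, 2000])
        groups = GroupSet()
        groups.add("OG1", [("sp", "g0"), ("sp", "g1"), ("sp", "ghost")])
        with pytest.warns(UserWarning, match="ghost"):
            clusters = detect_tandem_clusters(genes, groups)
        assert len(clusters) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_oracle_equivalence(self, seed):
        rng = random.Random(seed)
        genes, groups = random_instance(
            rng,
            n_genes=rng.randrange(50, 500),
            n_scaffolds=rng.randrange(1, 5),
            n_groups=rng.randrange(4, 20),
        )
        params = TandemParams()
        got = {
            (c.group_id, c.scaffold_id, tuple(c.member_gene_ids))
            for c in detect_tandem_clusters(genes, groups, params)
        }
        assert got == brute_force_clusters(genes, groups, params)


class TestSummary:
    def test_empty(self):
        assert tandem_summary([]) == (0, 0, {})

    def test_histogram(self):
        genes = make_genes([1 + i * 1500 for i in range(7)])
        groups = GroupSet()
        groups.add("A", [("sp", "g0"), ("sp", "g1")])
        groups.add("B", [("sp", "g2"), ("sp", "g3")])
        groups.add("C", [("sp", "g4"), ("sp", "g5"), ("sp", "g6")])
        clusters = detect_tandem_clusters(genes, groups)
        assert tandem_summary(clusters) == (3, 7, {2: 2, 3: 1})


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(3))
    def test_precision_recall_one(self, seed):
        params = SimParams(seed=seed, n_scaffolds=6, genes_per_scaffold=(60, 90),
                           n_families=20)
        _, genes, truth = simulate_annotation(params)
        clusters = detect_tandem_clusters(genes, truth_groupset(truth))
        planted = {tuple(m) for _, _, m in truth.tandem_arrays}
        found = {tuple(c.member_gene_ids) for c in clusters}
        assert found == planted
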