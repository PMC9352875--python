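"""Multimap ambiguity: simulation, placement search, minimal pruning."""

import itertools

import numpy as np
import pytest

from popgraph.fixtures import make_reference
from popgraph.graph_model import GenomeGraph, VariantRecord
from popgraph.multimap_filter import (
    PlacementIndex,
    _placement_table,
    detect_ambiguity,
    minimal_pruning_set,
    prune,
    prune_to_fixpoint,
    simulate_reads,
)


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _snp(bb, contig, pos, af=0.3):
    ref = bb[contig][pos - 1]
    return VariantRecord(contig, pos, ref, "A" if ref != "A" else "G", af=af)


class TestSimulateReads:
    def test_variant_free_contig_read_count(self):
        rng = np.random.default_rng(50)
        g = GenomeGraph({"c": _rand(rng, 1000)})
        reads = list(simulate_reads(g, L=150, stride=1))
        assert len(reads) == 1000 - 150 + 1
        assert len({r.origin for r in reads}) == len(reads)

    def test_single_snp_doubles_overlapping_windows(self):
        rng = np.random.default_rng(51)
        bb = {"c": _rand(rng, 600)}
        v = _snp(bb, "c", 300)
        g = GenomeGraph(bb, [v])
        reads = list(simulate_reads(g, L=100, stride=1))
        by_start = {}
        for r in reads:
            by_start.setdefault(r.origin.start, []).append(r)
        # windows overlapping the SNP (starts 200..299) spell two paths
        for s in range(205, 295):
            assert len(by_start[s]) == 2
        assert len(by_start[50]) == 1

    def test_insertion_interior_reads_emitted(self):
        rng = np.random.default_rng(52)
        bb = {"c": _rand(rng, 500)}
        tail = _rand(rng, 200)
        v = VariantRecord("c", 250, bb["c"][249], bb["c"][249] + tail, af=0.5)
        g = GenomeGraph(bb, [v])
        reads = list(simulate_reads(g, L=100, stride=1))
        interior = [r for r in reads if r.origin.alt_offset > 0]
        assert len(interior) == 200  # one per alt offset 1..200
        for r in interior:
            assert r.sequence in (v.alt + bb["c"][250:])  # substring check

    def test_stride_thins_backbone_windows(self):
        rng = np.random.default_rng(53)
        g = GenomeGraph({"c": _rand(rng, 400)})
        r1 = list(simulate_reads(g, L=50, stride=1))
        r5 = list(simulate_reads(g, L=50, stride=5))
        assert len(r5) == (len(r1) + 4) // 5


class TestFindPlacements:
    def test_unique_read_places_once(self):
        rng = np.random.default_rng(54)
        bb = {"c": _rand(rng, 800)}
        g = GenomeGraph(bb, [_snp(bb, "c", 400)])
        idx = PlacementIndex(g, L=80)
        read = bb["c"][100:180]
        (p,) = idx.find_placements(read)
        assert (p.contig, p.start, p.variants) == ("c", 100, ())

    def test_planted_duplication_places_twice(self):
        ref = make_reference(1, [2000], seed=55, planted_duplications=[(300, 1)])
        g = ref.graph()
        (contig, src, _, dst, ln) = ref.planted_duplications[0]
        read = g.backbone["chr1"][src + 50 : src + 50 + 150]
        placements = PlacementIndex(g, 150).find_placements(read)
        assert len(placements) >= 2
        starts = {p.start for p in placements}
        assert src + 50 in starts and dst + 50 in starts

    @pytest.mark.parametrize("seed", [60, 61])
    def test_exhaustive_equivalence_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        bb = {"c": _rand(rng, 900)}
        variants = [
            _snp(bb, "c", 200, af=0.2),
            VariantRecord("c", 450, bb["c"][449], bb["c"][449] + _rand(rng, 8),
                          af=0.4),
            VariantRecord("c", 700, bb["c"][699:704], bb["c"][699], af=0.6),
        ]
        g = GenomeGraph(bb, variants)
        L = 60
        table = _placement_table(g, L)  # brute-force spelling enumeration
        idx = PlacementIndex(g, L)
        probe = sorted(table)[:: max(1, len(table) // 60)]
        for seq in probe:
            assert set(idx.find_placements(seq)) == set(table[seq])


class TestDetectAmbiguity:
    def test_variant_free_unique_sequence_no_report(self):
        rng = np.random.default_rng(56)
        g = GenomeGraph({"c": _rand(rng, 800)})
        report = detect_ambiguity(g, L=100, stride=1)
        assert not report.ambiguous_reads and not report.backbone_repeats

    def test_backbone_repeat_reported_but_not_pruneable(self):
        ref = make_reference(1, [2000], seed=57, planted_duplications=[(250, 1)])
        g = ref.graph()
        report = detect_ambiguity(g, L=150, stride=1)
        assert report.backbone_repeats and not report.ambiguous_reads
        assert minimal_pruning_set(report, g) == set()

    def test_snp_creating_cross_locus_copy_implicates_variant(self):
        # a SNP alt converts locus A's window into a verbatim copy of locus B
        ref = make_reference(1, [2000], seed=58, planted_duplications=[(200, 1)])
        bb = dict(ref.backbone)
        (contig, src, _, dst, ln) = ref.planted_duplications[0]
        s = list(bb["chr1"])
        mid = dst + 100
        orig = s[mid]
        s[mid] = "A" if orig != "A" else "C"
        bb["chr1"] = "".join(s)
        vsnp = VariantRecord("chr1", mid + 1, s[mid], orig, af=0.1)
        g = GenomeGraph(bb, [vsnp])
        report = detect_ambiguity(g, L=150, stride=1)
        assert report.ambiguous_reads
        assert report.implicated_variants == {vsnp.key}

    def test_identical_insertions_both_implicated_one_pruned(self):
        rng = np.random.default_rng(59)
        bb = {"c": _rand(rng, 1500)}
        tail = _rand(rng, 250)
        va = VariantRecord("c", 300, bb["c"][299], bb["c"][299] + tail, af=0.3)
        vb = VariantRecord("c", 1000, bb["c"][999], bb["c"][999] + tail, af=0.2)
        g = GenomeGraph(bb, [va, vb])
        report = detect_ambiguity(g, L=120, stride=1)
        assert report.implicated_variants == {va.key, vb.key}
        target = minimal_pruning_set(report, g)
        assert len(target) == 1  # removing either copy resolves
        pruned, _ = prune(g, target)
        after = detect_ambiguity(pruned, L=120, stride=1)
        assert not [e for e in after.ambiguous_reads]


def _brute_force_min_size(report):
    """Independent minimum hitting-set-style search over the report."""
    entries = []
    for e in report.ambiguous_reads:
        immovable = {(p.contig, p.start) for p in e.placements if not p.variants}
        if len(immovable) > 1:
            continue  # unresolvable by pruning
        entries.append(e)
    if not entries:
        return 0
    cands = sorted(set().union(*(e.implicated for e in entries)))

    def ok(removed):
        for e in entries:
            locs = {(p.contig, p.start) for p in e.placements
                    if not (set(p.variants) & removed)}
            if len(locs) > 1:
                return False
        return True

    for size in range(len(cands) + 1):
        for combo in itertools.combinations(cands, size):
            if ok(set(combo)):
                return size
    raise AssertionError("unreachable")


class TestMinimalPruningSet:
    def test_single_read_single_snp(self):
        ref = make_reference(1, [1500], seed=62, planted_duplications=[(180, 1)])
        bb = dict(ref.backbone)
        (contig, src, _, dst, ln) = ref.planted_duplications[0]
        s = list(bb["chr1"])
        mid = dst + 90
        orig = s[mid]
        s[mid] = "A" if orig != "A" else "C"
        bb["chr1"] = "".join(s)
        vsnp = VariantRecord("chr1", mid + 1, s[mid], orig, af=0.1)
        g = GenomeGraph(bb, [vsnp])
        report = detect_ambiguity(g, L=150, stride=1)
        assert minimal_pruning_set(report, g) == {vsnp.key}

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_solver_matches_brute_force(self, seed):
        g, report = _random_ambiguous_instance(seed)
        target = minimal_pruning_set(report, g)
        assert len(target) == _brute_force_min_size(report)
        if target:
            pruned, _ = prune(g, target)
            after = detect_ambiguity(pruned, L=60, stride=1)
            assert not [
                e for e in after.ambiguous_reads
                if len({(p.contig, p.start) for p in e.placements
                        if not p.variants}) <= 1
            ]

    def test_objective_bp_prefers_small_variants(self):
        rng = np.random.default_rng(63)
        bb = {"c": _rand(rng, 1200)}
        tail = _rand(rng, 200)
        big = VariantRecord("c", 200, bb["c"][199], bb["c"][199] + tail, af=0.5)
        small = VariantRecord("c", 800, bb["c"][799], bb["c"][799] + tail, af=0.5)
        g = GenomeGraph(bb, [big, small])
        report = detect_ambiguity(g, L=100, stride=1)
        t_count = minimal_pruning_set(report, g, objective="count")
        t_bp = minimal_pruning_set(report, g, objective="bp")
        assert len(t_count) == 1 and len(t_bp) == 1  # symmetric case


def _random_ambiguous_instance(seed):
    """Duplicated segments with one copy mutated and restoring SNPs."""
    rng = np.random.default_rng(7000 + seed)
    ref = make_reference(1, [1500], seed=int(rng.integers(2**31)),
                         planted_duplications=[(90, 1), (90, 1)])
    seq = list(ref.backbone["chr1"])
    variants = {}
    for contig, src, _, dst, ln in ref.planted_duplications:
        for _ in range(int(rng.integers(1, 3))):
            off = int(rng.integers(10, ln - 10))
            orig = seq[dst + off]
            mutated = "A" if orig != "A" else "C"
            seq[dst + off] = mutated
            v = VariantRecord("chr1", dst + off + 1, mutated, orig,
                              af=float(rng.uniform(0.05, 0.6)))
            variants[v.key] = v
    g = GenomeGraph({"chr1": "".join(seq)}, variants.values())
    return g, detect_ambiguity(g, L=60, stride=1)


class TestPrune:
    def test_empty_set_identity(self, toy_graph):
        pruned, bp = prune(toy_graph, set())
        assert pruned.n_edges == toy_graph.n_edges and bp == 0

    def test_remove_all_leaves_linear_backbone(self, toy_graph):
        keys = {v.key for v in toy_graph.variants}
        pruned, bp = prune(toy_graph, keys)
        assert pruned.n_edges == 0
        assert bp == sum(v.length for v in toy_graph.variants)

    def test_unknown_variant_raises(self, toy_graph):
        with pytest.raises(KeyError):
            prune(toy_graph, {("chrX", 1, "A", "T")})

    def test_fixpoint_property(self):
        rng = np.random.default_rng(64)
        bb = {"c": _rand(rng, 1200)}
        tail = _rand(rng, 150)
        variants = [
            VariantRecord("c", 200, bb["c"][199], bb["c"][199] + tail, af=0.4),
            VariantRecord("c", 700, bb["c"][699], bb["c"][699] + tail, af=0.3),
            _snp(bb, "c", 1000),
        ]
        g = GenomeGraph(bb, variants)
        final, reports, removed, bp = prune_to_fixpoint(g, L=100, stride=1)
        assert len(removed) >= 1 and bp > 0
        last = detect_ambiguity(final, L=100, stride=1)
        pruneable = [
            e for e in last.ambiguous_reads
            if len({(p.contig, p.start) for p in e.placements
                    if not p.variants}) <= 1
        ]
        assert pruneable == []

    def test_pruning_never_adds_ambiguity(self):
        rng = np.random.default_rng(65)
        bb = {"c": _rand(rng, 1000)}
        tail = _rand(rng, 120)
        va = VariantRecord("c", 150, bb["c"][149], bb["c"][149] + tail, af=0.4)
        vb = VariantRecord("c", 600, bb["c"][599], bb["c"][599] + tail, af=0.3)
        vc = _snp(bb, "c", 900)
        g = GenomeGraph(bb, [va, vb, vc])
        before = {e.sequence for e in
                  detect_ambiguity(g, L=80, stride=1).ambiguous_reads}
        pruned, _ = prune(g, {va.key})
        after = {e.sequence for e in
                 detect_ambiguity(pruned, L=80, stride=1).ambiguous_reads}
        assert after <= before
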