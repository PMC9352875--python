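"""Source harmonization: splitting, normalization, decomposition, merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popgraph import io
from popgraph.fixtures import make_alt_contig, make_reference
from popgraph.graph_model import GenomeGraph, Region, VariantRecord, spell_haplotype
from popgraph.harmonize import (
    MultiAllelicSite,
    af_filter,
    decompose_alt_contigs,
    default_qc,
    harmonize_source,
    left_normalize,
    merge_sources,
    split_multiallelic,
)


class TestSplitMultiallelic:
    def test_two_alts_become_two_records(self):
        site = MultiAllelicSite("c", 10, "A", ["G", "T"], afs=[0.1, 0.2])
        a, b = split_multiallelic(site)
        assert (a.alt, a.af) == ("G", 0.1)
        assert (b.alt, b.af) == ("T", 0.2)
        assert a.pos == b.pos == 10

    def test_biallelic_passes_through(self):
        site = MultiAllelicSite("c", 5, "A", ["G"], afs=[0.3])
        (rec,) = split_multiallelic(site)
        assert rec.key == ("c", 5, "A", "G") and rec.af == 0.3

    def test_af_from_ac_an_when_missing(self):
        site = MultiAllelicSite("c", 5, "A", ["G"], acs=[3], an=100)
        (rec,) = split_multiallelic(site)
        assert rec.af == pytest.approx(0.03)

    def test_malformed_goes_to_rejection_log(self):
        log = []
        assert split_multiallelic(
            MultiAllelicSite("c", 5, "A", []), log
        ) == []
        assert split_multiallelic(
            MultiAllelicSite("c", 5, "A", ["<DEL>"]), log
        ) == []
        assert len(log) == 2

    def test_anchored_indel_alts_split_then_normalize_independently(self):
        bb = {"c": "TACCA"}
        site = MultiAllelicSite("c", 2, "AC", ["A", "ACC"])
        recs = [left_normalize(r, bb) for r in split_multiallelic(site)]
        # deletion of C and insertion of C, both left-aligned
        assert recs[0].key == ("c", 2, "AC", "A")
        assert recs[1].key == ("c", 2, "A", "AC")


class TestLeftNormalize:
    def test_snp_unchanged(self):
        v = VariantRecord("c", 3, "G", "T")
        assert left_normalize(v, {"c": "ACGTA"}) is v

    def test_equivalent_deletions_converge(self):
        # two representations of deleting 'CA' from the CACACA run
        bb = {"c": "GCACACAT"}
        v1 = VariantRecord("c", 3, "ACA", "A")
        v2 = VariantRecord("c", 5, "ACA", "A")
        n1 = left_normalize(v1, bb)
        n2 = left_normalize(v2, bb)
        assert n1.key == n2.key == ("c", 1, "GCA", "G")
        # both spell the same haplotype as the originals
        g = GenomeGraph(bb)
        region = Region("c", 0, 8)
        assert spell_haplotype(g, region, [n1]) == \
            spell_haplotype(g, region, [v1]) == "GCACAT"

    def test_leading_base_trim(self):
        bb = {"c": "ACGTACGT"}
        v = VariantRecord("c", 2, "CG", "CA")  # shared leading C
        n = left_normalize(v, bb)
        assert n.key == ("c", 3, "G", "A")

    def test_contig_start_stops_and_flags(self):
        bb = {"c": "AAAT"}
        flags = []
        v = VariantRecord("c", 1, "AA", "A")
        n = left_normalize(v, bb, flags)
        assert n.pos == 1 and flags

    @given(st.data())
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_idempotent_and_haplotype_preserving(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        seq = "".join(rng.choice(list("ACGT"), 60))
        bb = {"c": seq}
        pos = int(rng.integers(5, 40))
        width = int(rng.integers(1, 6))
        ref = seq[pos - 1 : pos - 1 + width]
        alt = ref[0] + "".join(rng.choice(list("ACGT"), int(rng.integers(0, 5))))
        v = VariantRecord("c", pos, ref, alt)
        n = left_normalize(v, bb)
        assert left_normalize(n, bb).key == n.key  # idempotent
        g = GenomeGraph(bb)
        lo = min(v.start, n.start)
        region = Region("c", max(0, lo - 5), min(len(seq), max(v.end, n.end) + 5))
        assert spell_haplotype(g, region, [n]) == spell_haplotype(g, region, [v])


@pytest.fixture()
def alt_contig_setup(tmp_path):
    ref = make_reference(1, [3000], seed=21)
    region = Region("chr1", 500, 1500)
    name, alt_seq, edits = make_alt_contig(
        ref, region, n_snps=3, indels=[4, -3, 60], seed=22
    )
    assembly = dict(ref.backbone)
    assembly[name] = alt_seq
    sam = tmp_path / "alt.sam"
    cigar = io.cigar_from_edits(len(region), edits)
    io.write_alt_contig_sam(
        sam, ref.backbone,
        [(name, alt_seq, region.contig, region.start, cigar)],
    )
    return ref, region, name, alt_seq, edits, assembly, str(sam)


class TestDecomposeAltContigs:
    def test_round_trip_reconstructs_alt_contig(self, alt_contig_setup):
        ref, region, name, alt_seq, edits, assembly, sam = alt_contig_setup
        primary, records, rejections = decompose_alt_contigs(assembly, sam)
        assert name not in primary and not rejections
        assert len(records) == len(edits)
        g = GenomeGraph(primary)
        respelled = spell_haplotype(g, region, records)
        assert respelled == alt_seq

    def test_sv_class_insertion_detected(self, alt_contig_setup):
        *_, assembly, sam = alt_contig_setup
        _, records, _ = decompose_alt_contigs(assembly, sam)
        assert any(r.var_class == "SV" and r.is_insertion for r in records)

    def test_identical_contig_yields_no_variants(self, tmp_path):
        ref = make_reference(1, [2000], seed=23)
        region = Region("chr1", 100, 900)
        seq = ref.backbone["chr1"][100:900]
        assembly = dict(ref.backbone)
        assembly["chr1_alt_x"] = seq
        sam = tmp_path / "same.sam"
        io.write_alt_contig_sam(sam, ref.backbone,
                                [("chr1_alt_x", seq, "chr1", 100, f"{len(seq)}=")])
        primary, records, rejections = decompose_alt_contigs(assembly, str(sam))
        assert records == [] and not rejections

    def test_unaligned_alt_contig_reported(self, tmp_path):
        ref = make_reference(1, [2000], seed=24)
        assembly = dict(ref.backbone)
        assembly["chr1_alt_lost"] = "ACGT" * 100
        sam = tmp_path / "empty.sam"
        io.write_alt_contig_sam(sam, ref.backbone, [])
        primary, records, rejections = decompose_alt_contigs(assembly, str(sam))
        assert "chr1_alt_lost" not in primary
        assert any(r.reason == "unaligned alt contig" for r in rejections)

    def test_plain_match_cigar_without_md_rejected(self, tmp_path):
        ref = make_reference(1, [2000], seed=25)
        seq = ref.backbone["chr1"][100:400]
        assembly = dict(ref.backbone)
        assembly["chr1_alt_m"] = seq
        sam = tmp_path / "m.sam"
        io.write_alt_contig_sam(sam, ref.backbone,
                                [("chr1_alt_m", seq, "chr1", 100, "300M")])
        with pytest.raises(ValueError, match="MD"):
            decompose_alt_contigs(assembly, str(sam))


class TestMergeSources:
    def test_single_source_identity(self):
        recs = [VariantRecord("c", 5, "A", "G", af=0.5, source="x")]
        out = merge_sources([(recs, 10)])
        assert len(out) == 1 and out[0].af == 0.5

    def test_ac_an_pooling(self):
        a = [VariantRecord("c", 5, "A", "G", ac=3, an=100, af=0.03, source="a")]
        b = [VariantRecord("c", 5, "A", "G", ac=7, an=100, af=0.07, source="b")]
        (rec,) = merge_sources([(a, 50), (b, 50)])
        assert rec.af == pytest.approx(0.05)
        assert rec.ac == 10 and rec.an == 200
        assert rec.source == "a,b"

    def test_weighted_mean_fallback(self):
        a = [VariantRecord("c", 5, "A", "G", af=0.10, source="a")]
        b = [VariantRecord("c", 5, "A", "G", af=0.40, source="b")]
        (rec,) = merge_sources([(a, 100), (b, 300)])
        assert rec.af == pytest.approx(0.325)

    def test_order_independence(self):
        a = [VariantRecord("c", 5, "A", "G", af=0.1, source="a"),
             VariantRecord("c", 9, "T", "C", af=0.2, source="a")]
        b = [VariantRecord("c", 5, "A", "G", af=0.3, source="b")]
        fwd = merge_sources([(a, 10), (b, 20)])
        rev = merge_sources([(b, 20), (a, 10)])
        assert [(r.key, r.af, r.source) for r in fwd] == \
            [(r.key, r.af, r.source) for r in rev]


class TestAFFilter:
    @pytest.mark.parametrize("af,kept", [(0.05, True), (0.049, False),
                                         (0.9, True), (0.0, False)])
    def test_boundary_inclusive(self, af, kept):
        rec = VariantRecord("c", 5, "A", "G", af=af)
        out = af_filter([rec], 0.05)
        assert (len(out) == 1) is kept

    def test_missing_af_dropped_and_logged(self):
        log = []
        out = af_filter([VariantRecord("c", 5, "A", "G")], 0.05, log)
        assert out == [] and log[0].reason == "missing AF"

    def test_empty_input(self):
        assert af_filter([], 0.05) == []


class TestHarmonizeSource:
    def test_qc_filters_non_pass_sites(self):
        bb = {"c": "ACGTACGT"}
        sites = [
            MultiAllelicSite("c", 2, "C", ["T"], afs=[0.5], filter="PASS"),
            MultiAllelicSite("c", 4, "T", ["A"], afs=[0.5], filter="LowQual"),
            MultiAllelicSite("c", 6, "C", ["G"], afs=[0.5]),
        ]
        log = []
        out = harmonize_source(sites, bb, rejections=log)
        assert [r.pos for r in out] == [2, 6]
        assert len(log) == 1 and log[0].stage == "qc"

    def test_default_qc_predicate(self):
        assert default_qc(MultiAllelicSite("c", 1, "A", ["G"], filter=None))
        assert default_qc(MultiAllelicSite("c", 1, "A", ["G"], filter="PASS"))
        assert not default_qc(MultiAllelicSite("c", 1, "A", ["G"], filter="q10"))
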