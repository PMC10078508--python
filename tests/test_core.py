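"""Layout arithmetic, feature sizes, and start/stop classification."""

import pytest
from hypothesis import given, strategies as st

from mitochar import formats, synthetic
from mitochar.core import (
    GeneFeature, MalformedCdsError, MitogenomeRecord, classify_ends,
    feature_length, intergenic, layout_report,
)


@pytest.mark.parametrize("name,strand,start,stop,expected", [
    ("cox1", "J", 1437, 2981, 1545),
    ("atp8", "J", 3886, 4044, 159),
    ("trnI", "J", 7, 7, 1),
])
def test_feature_length_non_wrapping(name, strand, start, stop, expected):
    f = GeneFeature(name=name, strand=strand, start=start, stop=stop)
    assert feature_length(f, 15655) == expected


def test_feature_length_wrapping_feature():
    f = GeneFeature(name="d-loop", strand="J", start=15600, stop=100, wraps=True)
    assert feature_length(f, 15655) == 56 + 100


def test_feature_length_rejects_out_of_range():
    f = GeneFeature(name="x", strand="J", start=10, stop=20)
    with pytest.raises(ValueError):
        feature_length(f, 15)


@pytest.mark.parametrize("prev,nxt,expected", [
    # longest spacer and deepest overlap of the reference architecture
    (("trnS2", 11501, 11573), ("nad1", 11597, 12535), 23),
    (("nad4", 8124, 9461), ("nad4l", 9455, 9742), -7),
    (("a", 1, 100), ("b", 101, 200), 0),
])
def test_intergenic_pairs(prev, nxt, expected):
    fp = GeneFeature(name=prev[0], strand="J", start=prev[1], stop=prev[2])
    fn = GeneFeature(name=nxt[0], strand="J", start=nxt[1], stop=nxt[2])
    assert intergenic(fp, fn) == expected


def test_intergenic_wrap_around_pair():
    last = GeneFeature(name="d-loop", strand="J", start=14785, stop=15655)
    first = GeneFeature(name="trnI", strand="J", start=1, stop=65)
    assert intergenic(last, first, genome_length=15655) == 0


class TestReferenceLayout:
    """The bundled 38-feature annotation table, recomputed from coordinates."""

    def test_strand_tallies(self, reference_record):
        lay = layout_report(reference_record)
        assert lay.j_gene_count == 23
        assert lay.strand_tallies[("J", "PCG")] == 9
        assert lay.strand_tallies[("J", "tRNA")] == 14
        assert lay.strand_tallies[("N", "PCG")] == 4
        assert lay.strand_tallies[("N", "tRNA")] == 8
        assert lay.strand_tallies[("N", "rRNA")] == 2

    def test_extremes(self, reference_record):
        lay = layout_report(reference_record)
        assert lay.longest_spacer == ("trnS2", "nad1", 23)
        # coordinate-derived view: trnW/trnC overlap by 8 (printed with the
        # wrong sign in annotation tables); nad4/nad4l is the deepest PCG pair
        assert lay.longest_overlap_non_rrna == ("trnW", "trnC", -8)
        pair = {(g.prev, g.next): g.value for g in lay.gaps}
        assert pair[("nad4", "nad4l")] == -7

    def test_rrna_overlaps_reported_separately(self, reference_record):
        lay = layout_report(reference_record)
        values = sorted(g.value for g in lay.rrna_overlaps)
        assert values == [-42, -18]
        assert lay.overlap_count == lay.overlap_count_non_rrna + 2

    def test_sizes_reproduce_annotation_table(self, reference_record):
        # every printed Size cell re-derives from Start/Stop exactly
        printed = {
            r["name"]: int(r["stop"]) - int(r["start"]) + 1
            if r["strand"] == "J" else abs(int(r["stop"]) - int(r["start"])) + 1
            for r in formats.load_reference_rows()
        }
        lay = layout_report(reference_record)
        for r in formats.load_reference_rows():
            name = formats.canonical_name(r["name"])
            assert lay.sizes[name] == printed[r["name"]]

    def test_conservation_identity(self, reference_record):
        assert layout_report(reference_record).conservation_residual() == 0


def test_layout_zero_overlap_conservation():
    feats = [
        GeneFeature(name=f"g{i}", strand="J", start=1 + i * 120, stop=100 + i * 120)
        for i in range(5)
    ]
    m = MitogenomeRecord(id="toy", length=620, features=feats)
    lay = layout_report(m)
    assert lay.overlap_count == 0
    assert sum(lay.sizes.values()) + sum(g.value for g in lay.gaps) == 620


@given(st.integers(min_value=0, max_value=10_000))
def test_conservation_identity_random_layouts(seed):
    lay = layout_report(synthetic.random_layout(seed=seed))
    assert lay.conservation_residual() == 0


class TestClassifyEnds:
    def test_truncated_single_t_stop(self):
        # a 667-bp CDS ending in T carries the polyadenylation-completed stop
        cds = "ATA" + "GCT" * 221 + "T"
        assert len(cds) == 667
        cls = classify_ends(cds)
        assert (cls.start_codon, cls.stop_codon, cls.complete) == ("ATA", "T--", False)

    def test_gtg_start_complete_tag_stop(self):
        cds = "GTG" + "GCA" * 444 + "TAG"
        assert len(cds) == 1338
        cls = classify_ends(cds)
        assert (cls.start_codon, cls.stop_codon, cls.complete) == ("GTG", "TAG", True)

    def test_minimal_complete_cds(self):
        cls = classify_ends("ATGTAA")
        assert (cls.start_codon, cls.stop_codon, cls.complete) == ("ATG", "TAA", True)

    def test_ta_dash_stop(self):
        cls = classify_ends("ATG" + "GGT" * 4 + "TA")
        assert (cls.stop_codon, cls.complete) == ("TA-", False)

    def test_malformed_trailing_base(self):
        with pytest.raises(MalformedCdsError):
            classify_ends("ATGGGTA" + "AC")  # mod 3 == 0 but no stop... length 9
        with pytest.raises(MalformedCdsError):
            classify_ends("ATGGGTG")  # mod 3 == 1, trailing G

    @given(st.integers(min_value=2, max_value=60),
           st.sampled_from(["TAA", "TAG"]),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_complete_cds_always_complete(self, n_codons, stop, seed):
        cds = synthetic.random_cds(n_codons, seed=seed) + stop
        cls = classify_ends(cds)
        assert cls.complete and cls.stop_codon == stop


def test_record_completeness_requires_37_genes(reference_record):
    assert reference_record.complete
    fewer = MitogenomeRecord(
        id="partial", length=reference_record.length,
        features=reference_record.features[:-2],
    )
    assert not fewer.complete


def test_sequence_required_error(reference_record):
    with pytest.raises(ValueError, match="sequence required"):
        reference_record.extract(reference_record.features[0])
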