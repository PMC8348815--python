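import pytest

from tdnarray.annotation import AnnotationSegment, ReadAnnotation
from tdnarray.detection import ReferenceCatalog
from tdnarray.loci import (
    ChainUnit,
    RawUnit,
    flip_chain,
    _internal_junctions,
    border_status,
    classify_event,
    cluster_loci,
    estimate_zygosity,
    FlankAnchor,
    InsertionStructure,
)
from tdnarray.records import SeqRecord


def seg(q0, q1, category, subject, s0, s1, strand="+"):
    return AnnotationSegment(q0, q1, category, subject, s0, s1, strand, 1000)


def ann(read_id, read_len, segments, gaps=()):
    return ReadAnnotation(read_id, read_len, segments, list(gaps))


class TestClusterLoci:
    def test_changeovers_within_window_share_locus(self):
        a1 = ann(
            "r1",
            10_000,
            [
                seg(0, 5000, "NUCLEAR", "chr1", 27_737_100, 27_742_100),
                seg(5000, 9000, "TDNA", "td", 0, 4000),
            ],
        )
        a2 = ann(
            "r2",
            10_000,
            [
                seg(0, 4000, "NUCLEAR", "chr1", 27_738_350, 27_742_350),
                seg(4000, 9000, "TDNA", "td", 0, 5000),
            ],
        )
        groups, unanchored = cluster_loci([a1, a2])
        assert len(groups) == 1 and not unanchored
        assert {x.read_id for x in groups[0].annotations} == {"r1", "r2"}

    def test_four_mbp_apart_are_distinct_loci(self):
        a1 = ann(
            "r1",
            9000,
            [
                seg(0, 4000, "NUCLEAR", "chr2", 1_000_000, 1_004_000),
                seg(4000, 8000, "TDNA", "td", 0, 4000),
            ],
        )
        a2 = ann(
            "r2",
            9000,
            [
                seg(0, 4000, "NUCLEAR", "chr2", 4_996_000, 5_000_000),
                seg(4000, 8000, "TDNA", "td", 0, 4000),
            ],
        )
        groups, _ = cluster_loci([a1, a2])
        assert len(groups) == 2

    def test_empty_input(self):
        groups, unanchored = cluster_loci([])
        assert groups == [] and unanchored == []

    def test_read_without_genomic_segment_is_unanchored(self):
        a = ann("r", 5000, [seg(0, 4000, "TDNA", "td", 0, 4000)])
        groups, unanchored = cluster_loci([a])
        assert groups == [] and [x.read_id for x in unanchored] == ["r"]


@pytest.fixture(scope="module")
def vector_catalog():
    return ReferenceCatalog(
        [SeqRecord("chr1", "ACGT" * 2500), SeqRecord("vec", "ACGT" * 1500)],
        {"chr1": "NUCLEAR", "vec": "TDNA"},
    )


class TestBorderStatus:
    def test_start_within_slack_of_lb_is_intact(self, vector_catalog, config):
        # transferred DNA starting at vector position 4 (1-based): LB intact
        chain = [ChainUnit("TDNA", "vec", 3, 5000, "+")]
        border_status(chain, vector_catalog, config)
        assert chain[0].border_left == "LB_INTACT"

    def test_end_far_from_rb_is_truncated(self, vector_catalog, config):
        vec_len = vector_catalog.length("vec")
        chain = [ChainUnit("TDNA", "vec", 3, vec_len - 1200, "+")]
        border_status(chain, vector_catalog, config)
        assert chain[0].border_right == "RB_TRUNCATED"

    def test_rb_intact_at_vector_end(self, vector_catalog, config):
        vec_len = vector_catalog.length("vec")
        chain = [ChainUnit("TDNA", "vec", 200, vec_len - 2, "+")]
        border_status(chain, vector_catalog, config)
        assert chain[0].border_right == "RB_INTACT"
        assert chain[0].border_left == "LB_TRUNCATED"

    def test_minus_unit_borders_swap(self, vector_catalog, config):
        chain = [ChainUnit("TDNA", "vec", 2, 5000, "-")]
        border_status(chain, vector_catalog, config)
        assert chain[0].border_right == "LB_INTACT"

    def test_head_to_head_units_meet_rb_to_rb(self, vector_catalog, config):
        chain = [
            ChainUnit("GENOMIC", "chr1", 0, 5000, "+"),
            ChainUnit("TDNA", "vec", 3, 5500, "+"),
            ChainUnit("TDNA", "vec", 100, 5400, "-"),
            ChainUnit("GENOMIC", "chr1", 5010, 9000, "+"),
        ]
        border_status(chain, vector_catalog, config)
        assert _internal_junctions(chain) == ["RB_RB"]
        assert chain[1].border_right == "INTERNAL"
        assert chain[1].border_left == "LB_INTACT"


class TestClassifyEvent:
    def _structure(self, lf, rf, chain, locus="L"):
        return InsertionStructure(locus, lf, rf, chain, ["r1", "r2"])

    def test_flanks_on_different_chromosomes(self):
        st = self._structure(
            FlankAnchor("chr3", 6_000_000, "LEFT_OF_INSERT", 5),
            FlankAnchor("chr5", 23_000_000, "RIGHT_OF_INSERT", 5),
            [
                ChainUnit("GENOMIC", "chr3", 5_990_000, 6_000_000, "+"),
                ChainUnit("TDNA", "vec", 3, 5500, "+"),
                ChainUnit("GENOMIC", "chr5", 23_000_000, 23_010_000, "+"),
            ],
        )
        (call,) = classify_event([st])
        assert call.event_type == "TRANSLOCATION_FUSION"
        assert {p[0] for p in call.partners} == {"chr3", "chr5"}

    def test_single_tdna_unit_is_canonical(self):
        st = self._structure(
            FlankAnchor("chr1", 100, "LEFT_OF_INSERT", 5),
            FlankAnchor("chr1", 113, "RIGHT_OF_INSERT", 5),
            [
                ChainUnit("GENOMIC", "chr1", 0, 100, "+"),
                ChainUnit("TDNA", "vec", 3, 5500, "+"),
                ChainUnit("GENOMIC", "chr1", 113, 300, "+"),
            ],
        )
        (call,) = classify_event([st])
        assert call.event_type == "CANONICAL_INSERTION"

    def test_multi_unit_is_complex_array(self):
        st = self._structure(
            FlankAnchor("chr1", 100, "LEFT_OF_INSERT", 5),
            FlankAnchor("chr1", 113, "RIGHT_OF_INSERT", 5),
            [
                ChainUnit("GENOMIC", "chr1", 0, 100, "+"),
                ChainUnit("TDNA", "vec", 3, 5500, "+"),
                ChainUnit("BVB", "bvb", 0, 1000, "+"),
                ChainUnit("GENOMIC", "chr1", 113, 300, "+"),
            ],
        )
        (call,) = classify_event([st])
        assert call.event_type == "COMPLEX_ARRAY"

    def test_reciprocal_translocations_are_paired(self):
        st1 = self._structure(
            FlankAnchor("chr3", 6_000_000, "LEFT_OF_INSERT", 5),
            FlankAnchor("chr5", 23_000_000, "RIGHT_OF_INSERT", 5),
            [
                ChainUnit("GENOMIC", "chr3", 5_990_000, 6_000_000, "+"),
                ChainUnit("TDNA", "vec", 3, 5500, "+"),
                ChainUnit("GENOMIC", "chr5", 23_000_000, 23_010_000, "+"),
            ],
            locus="L1",
        )
        st2 = self._structure(
            FlankAnchor("chr5", 23_000_500, "LEFT_OF_INSERT", 4),
            FlankAnchor("chr3", 6_000_200, "RIGHT_OF_INSERT", 4),
            [
                ChainUnit("GENOMIC", "chr5", 22_990_000, 23_000_500, "+"),
                ChainUnit("GENOMIC", "chr3", 6_000_200, 6_010_000, "+"),
            ],
            locus="L2",
        )
        calls = classify_event([st1], [st2])
        types = {c.locus_id: c for c in calls}
        assert types["L1"].event_type == "TRANSLOCATION_FUSION"
        assert types["L2"].event_type == "TDNA_FREE_FUSION"
        assert "reciprocal_with=L2" in types["L1"].notes
        assert "reciprocal_with=L1" in types["L2"].notes


class TestZygosity:
    def test_one_third_wild_type_is_segregating(self):
        z = estimate_zygosity("L", wt_spanning=5, insert_supporting=10)
        assert z.wt_allele_read_fraction == pytest.approx(1 / 3)
        assert z.call == "SEGREGATING"

    def test_no_wild_type_reads_is_homozygous(self):
        assert estimate_zygosity("L", 0, 20).call == "HOMOZYGOUS"

    def test_low_depth_undetermined(self):
        assert estimate_zygosity("L", 2, 2).call == "UNDETERMINED"

    def test_excess_wild_type_undetermined(self):
        assert estimate_zygosity("L", 15, 5).call == "UNDETERMINED"


def test_flip_chain_is_an_involution():
    chain = [
        RawUnit("GENOMIC", "chr1", 100, 900, "+", "r", reliable_left=False),
        RawUnit("TDNA", "vec", 3, 5500, "-", "r", low_quality=True),
        RawUnit("GENOMIC", "chr1", 910, 2000, "+", "r"),
    ]
    # give the units their chain-space neighbour context
    for i, u in enumerate(chain):
        u.prev_kind = chain[i - 1].kind if i else None
        u.next_kind = chain[i + 1].kind if i < len(chain) - 1 else None
    twice = flip_chain(flip_chain(chain))
    assert [
        (u.kind, u.subject, u.s_start, u.s_end, u.orient, u.reliable_left,
         u.reliable_right, u.low_quality, u.prev_kind, u.next_kind)
        for u in twice
    ] == [
        (u.kind, u.subject, u.s_start, u.s_end, u.orient, u.reliable_left,
         u.reliable_right, u.low_quality, u.prev_kind, u.next_kind)
        for u in chain
    ]
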