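import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdnarray.alignment import ScoringScheme, build_index, evalue
from tdnarray.detection import PipelineConfig, ReferenceCatalog
from tdnarray.junctions import (
    JunctionWindow,
    classify_filler,
    enumerate_junctions,
    find_microhomology,
)
from tdnarray.loci import ChainUnit, InsertionStructure
from tdnarray.records import SeqRecord
from conftest import random_seq


def brute_force_overlap(left: str, right: str) -> int:
    best = 0
    for k in range(1, min(len(left), len(right)) + 1):
        if left[len(left) - k :] == right[:k]:
            best = k
    return best


class TestMicrohomology:
    def test_known_overlap(self):
        assert find_microhomology("TTGGACGT", "ACGTTCAA") == 4

    def test_identical_sequences(self):
        s = "ACGTACGTACGTACGTACGT"
        assert find_microhomology(s, s) == 20

    def test_blunt_junction(self):
        assert find_microhomology("AAAA", "CCCC") == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            find_microhomology("", "ACGT")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        left = random_seq(rng, 50)
        right = random_seq(rng, 50)
        assert find_microhomology(left, right) == brute_force_overlap(left, right)


@pytest.fixture(scope="module")
def junction_catalog():
    rng = np.random.default_rng(7)
    return ReferenceCatalog(
        [
            SeqRecord("chrA", random_seq(rng, 20_000)),
            SeqRecord("plastome", random_seq(rng, 3_000)),
            SeqRecord("tdna", random_seq(rng, 4_000)),
        ],
        {"chrA": "NUCLEAR", "plastome": "PLASTOME", "tdna": "TDNA"},
    )


class TestClassifyFiller:
    def _window(
        self,
        catalog,
        filler,
        left_at=10_000,
        right_at=10_010,
        ctx=100,
        right_subject=None,
    ):
        chrom = catalog.seq("chrA")
        if right_subject is None:
            right = chrom[right_at : right_at + ctx]
            right_origin = ("GENOMIC", "chrA", right_at, "+")
        else:
            right = catalog.seq(right_subject)[right_at : right_at + ctx]
            kind = "TDNA" if right_subject == "tdna" else "GENOMIC"
            right_origin = (kind, right_subject, right_at, "+")
        seq = chrom[left_at - ctx : left_at] + filler + right
        return JunctionWindow(
            junction_id="J",
            seq=seq,
            left_origin=("GENOMIC", "chrA", left_at, "+"),
            right_origin=right_origin,
            left_end=ctx,
            right_start=ctx + len(filler),
        )

    def test_long_organellar_filler_found_at_stage_one(self, junction_catalog, config):
        filler = junction_catalog.seq("plastome")[1000:1652]
        window = self._window(junction_catalog, filler)
        index = build_index(junction_catalog.records, config.kmer)
        report = classify_filler(window, junction_catalog, index, config)
        assert abs(len(report.filler_seq) - 652) <= 10
        assert report.filler_origin_hits
        assert report.filler_origin_hits[0].subject_id == "plastome"

    def test_blunt_junction_has_no_filler(self, junction_catalog, config):
        window = self._window(junction_catalog, "")
        index = build_index(junction_catalog.records, config.kmer)
        report = classify_filler(window, junction_catalog, index, config)
        assert report.filler_seq == ""
        assert report.filler_origin_hits == []

    def test_nine_bp_filler_needs_short_match_stage(self, junction_catalog, config):
        """A 9 bp filler at a genome::T-DNA junction (no gapped bridging
        possible across heterologous origins) is invisible to the seeded
        stage-1 search; the permissive short-match stage recovers it when
        the expectation value allows (Karlin-Altschul formula)."""
        filler = junction_catalog.seq("plastome")[2000:2009]
        scheme = ScoringScheme()
        db_len = sum(len(r.bases) for r in junction_catalog.records)
        # the catalog is small enough that a perfect 9-mer passes E <= 10
        e_bare = evalue(9 * scheme.match, 9, db_len, scheme)
        assert e_bare <= config.filler_evalue
        window = self._window(
            junction_catalog, filler, right_at=500, right_subject="tdna"
        )
        index = build_index(junction_catalog.records, config.kmer)
        report = classify_filler(window, junction_catalog, index, config)
        # flank alignments may nibble a base or two off the filler ends
        assert 6 <= len(report.filler_seq) <= 9
        assert report.filler_origin_hits, "short-match stage should recover origin"

    def test_idempotent(self, junction_catalog, config):
        filler = junction_catalog.seq("plastome")[1000:1100]
        window = self._window(junction_catalog, filler)
        index = build_index(junction_catalog.records, config.kmer)
        r1 = classify_filler(window, junction_catalog, index, config)
        r2 = classify_filler(window, junction_catalog, index, config)
        assert (r1.filler_seq, r1.microhomology_len) == (r2.filler_seq, r2.microhomology_len)
        assert [h.subject_id for h in r1.filler_origin_hits] == [
            h.subject_id for h in r2.filler_origin_hits
        ]


class TestEnumerateJunctions:
    def test_point_junctions_around_tdna(self):
        st = InsertionStructure(
            "L",
            None,
            None,
            [
                ChainUnit("GENOMIC", "chrA", 0, 5000, "+"),
                ChainUnit("TDNA", "tdna", 3, 3900, "+"),
                ChainUnit("GENOMIC", "chrA", 5010, 9000, "+"),
            ],
            ["r"],
        )
        assert enumerate_junctions(st) == [(0, 1), (1, 2)]

    def test_short_organellar_insert_is_one_composite_junction(self):
        st = InsertionStructure(
            "L",
            None,
            None,
            [
                ChainUnit("GENOMIC", "chrA", 0, 5000, "+"),
                ChainUnit("CPDNA", "plastome", 1000, 1652, "+"),
                ChainUnit("GENOMIC", "chrA", 5010, 9000, "+"),
            ],
            ["r"],
        )
        assert enumerate_junctions(st) == [(0, 2)]
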