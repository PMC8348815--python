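import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdnarray.annotation import (
    ReadAnnotation,
    find_gaps,
    flag_quality_drop,
    sliding_phred,
    tile_annotation,
)
from tdnarray.detection import PipelineConfig
from tdnarray.records import LocalHit, SeqRecord


def make_hit(q0, q1, score, subject="s", strand="+", query="q"):
    return LocalHit(
        query_id=query,
        q_start=q0,
        q_end=q1,
        strand=strand,
        subject_id=subject,
        s_start=q0,
        s_end=q1,
        identity=0.9,
        score=score,
        evalue=1e-60,
        aln_len=q1 - q0,
    )


class TestTiling:
    def test_overlap_of_exactly_ten_is_kept(self, config):
        h1 = make_hit(0, 1000, 900)
        h2 = make_hit(990, 1500, 450)
        segs = tile_annotation([h1, h2], 1500, config)
        assert [(s.q_start, s.q_end) for s in segs] == [(0, 1000), (990, 1500)]

    def test_overlap_above_ten_discards_lower_score(self, config):
        h1 = make_hit(0, 1000, 900)
        h3 = make_hit(985, 1500, 450)
        segs = tile_annotation([h1, h3], 1500, config)
        assert [(s.q_start, s.q_end) for s in segs] == [(0, 1000)]

    def test_greedy_cascade(self, config):
        """Accept by decreasing score; each rejection is against already
        accepted segments only."""
        hits = [make_hit(0, 100, 50), make_hit(50, 150, 60), make_hit(120, 200, 40)]
        segs = tile_annotation(hits, 200, config)
        assert [(s.q_start, s.q_end) for s in segs] == [(50, 150)]

    def test_order_independent(self, config):
        hits = [
            make_hit(0, 500, 700),
            make_hit(480, 900, 650, subject="t"),
            make_hit(100, 600, 660),
            make_hit(890, 1200, 400),
        ]
        expected = tile_annotation(hits, 1200, config)
        for perm in itertools.permutations(hits):
            got = tile_annotation(list(perm), 1200, config)
            assert [(s.q_start, s.q_end, s.subject_id) for s in got] == [
                (s.q_start, s.q_end, s.subject_id) for s in expected
            ]

    def test_segments_are_subset_with_unchanged_coordinates(self, config):
        hits = [make_hit(i * 90, i * 90 + 100, 100 + i) for i in range(8)]
        segs = tile_annotation(hits, 1000, config)
        original = {(h.q_start, h.q_end) for h in hits}
        assert all((s.q_start, s.q_end) in original for s in segs)

    def test_multiple_queries_rejected(self, config):
        with pytest.raises(ValueError):
            tile_annotation(
                [make_hit(0, 100, 10), make_hit(0, 100, 10, query="other")], 100, config
            )


class TestGaps:
    def test_internal_gap(self, config):
        segs = tile_annotation(
            [make_hit(0, 2000, 900), make_hit(3500, 6000, 800)], 6000, config
        )
        assert find_gaps(segs, 6000, config) == [(2000, 3500)]

    def test_full_coverage_no_gap(self, config):
        segs = tile_annotation([make_hit(0, 6000, 900)], 6000, config)
        assert find_gaps(segs, 6000, config) == []

    def test_sub_kbp_gap_not_reported(self, config):
        segs = tile_annotation(
            [make_hit(0, 2000, 900), make_hit(2800, 6000, 800)], 6000, config
        )
        assert find_gaps(segs, 6000, config) == []

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 30)), max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_cover_plus_gaps_account_for_read(self, spans):
        config = PipelineConfig()
        hits = []
        read_len = 10_000
        for i, (start100, width100) in enumerate(spans):
            q0, q1 = start100 * 100, min(read_len, (start100 + width100) * 100)
            if q1 > q0:
                hits.append(make_hit(q0, q1, 100 + i))
        segs = tile_annotation(hits, read_len, config)
        gaps = find_gaps(segs, read_len, config)
        covered = np.zeros(read_len, bool)
        for s in segs:
            covered[s.q_start : s.q_end] = True
        for g0, g1 in gaps:
            assert g1 - g0 > config.unannotated_min_bp
            # gaps never overlap accepted segments by more than edge slack
            assert covered[g0 + 11 : g1 - 11].sum() == 0


class TestSlidingPhred:
    def test_constant_quality(self, config):
        read = SeqRecord("r", "A" * 500, quals=[12] * 500)
        track = sliding_phred(read, config)
        assert len(track.means) == 4
        assert all(m == 12.0 for m in track.means)

    def test_short_read_requires_flag(self, config):
        read = SeqRecord("r", "A" * 150, quals=[9] * 150)
        with pytest.raises(ValueError):
            sliding_phred(read, config)
        track = sliding_phred(read, config, allow_short=True)
        assert track.means == [9.0]

    def test_quality_step_is_monotone_across_transition(self, config):
        quals = [20] * 300 + [7] * 200
        read = SeqRecord("r", "A" * 500, quals=quals)
        track = sliding_phred(read, config)
        assert all(a >= b for a, b in zip(track.means, track.means[1:]))

    def test_missing_quals(self, config):
        with pytest.raises(ValueError):
            sliding_phred(SeqRecord("r", "A" * 500), config)


class TestQualityDropFlag:
    def _annotation(self, segs, gaps, read_len=8000):
        return ReadAnnotation("r", read_len, segs, gaps)

    def test_low_quality_gap_between_tdna_is_inverted_arm(self, config):
        quals = [13] * 3000 + [6] * 3000 + [13] * 2000
        read = SeqRecord("r", "A" * 8000, quals=quals)
        track = sliding_phred(read, config)
        h1 = make_hit(0, 3000, 900)
        h2 = make_hit(6000, 8000, 800)
        segs = tile_annotation([h1, h2], 8000, config)
        for s in segs:
            s.category = "TDNA"
        ann = self._annotation(segs, [(3000, 6000)])
        (verdict,) = flag_quality_drop(track, ann, config)
        assert verdict.verdict == "CANDIDATE_INVERTED_ARM"
        assert verdict.mean_phred < 8

    def test_high_quality_gap_unexplained(self, config):
        read = SeqRecord("r", "A" * 8000, quals=[13] * 8000)
        track = sliding_phred(read, config)
        segs = tile_annotation([make_hit(0, 3000, 900)], 8000, config)
        ann = self._annotation(segs, [(3000, 8000)])
        (verdict,) = flag_quality_drop(track, ann, config)
        assert verdict.verdict == "UNEXPLAINED"

    def test_no_gaps_empty(self, config):
        read = SeqRecord("r", "A" * 500, quals=[13] * 500)
        track = sliding_phred(read, config)
        ann = self._annotation([], [])
        assert flag_quality_drop(track, ann, config) == []
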