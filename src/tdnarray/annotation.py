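"""Greedy tiling annotation of reads and sliding-window quality tracks.

Hits are laid onto the read one after another in decreasing-score order;
a hit is discarded iff its read-interval overlap with any previously
accepted segment exceeds 10 bp.  Unannotated stretches longer than 1 kbp
are exposed as gaps and cross-referenced with a 200 nt / 100 nt sliding
mean-Phred track: low-quality gaps flanked by T-DNA are candidates for the
poorly-sequenced second arm of an inverted repeat.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import ScoringScheme, SeedIndex, find_local_hits
from .detection import PipelineConfig, ReferenceCatalog
from .records import LocalHit, SeqRecord


@dataclass
class AnnotationSegment:
    q_start: int
    q_end: int
    category: str
    subject_id: str
    s_start: int
    s_end: int
    strand: str
    score: int
    mean_phred: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.q_start < self.q_end:
            raise ValueError("segment q_start must be < q_end")

    def __len__(self) -> int:
        return self.q_end - self.q_start


@dataclass
class ReadAnnotation:
    read_id: str
    read_len: int
    segments: list[AnnotationSegment]
    gaps: list[tuple[int, int]]


@dataclass
class QualityTrack:
    read_id: str
    window_nt: int
    step_nt: int
    means: list[float]

    def window_interval(self, i: int) -> tuple[int, int]:
        return i * self.step_nt, i * self.step_nt + self.window_nt


def _tile_sort_key(h: LocalHit):
    # decreasing score; ties: longer alignment, smaller q_start, subject id
    return (-h.score, -h.aln_len, h.q_start, h.subject_id, h.strand)


def tile_annotation(
    hits: Sequence[LocalHit],
    read_len: int,
    config: Optional[PipelineConfig] = None,
    catalog: Optional[ReferenceCatalog] = None,
) -> list[AnnotationSegment]:
    """Greedy non-conflicting tiling of hits onto the read.

    A hit is discarded iff its overlap with any previously accepted segment
    exceeds ``tile_max_overlap_bp`` (10 bp; an exactly-10 bp overlap is
    kept).  Output is sorted by q_start and is independent of input order.
    """
    config = config or PipelineConfig()
    if not hits:
        return []
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits from multiple queries: {sorted(queries)}")
    accepted: list[LocalHit] = []
    for h in sorted(hits, key=_tile_sort_key):
        conflict = False
        for seg in accepted:
            overlap = min(h.q_end, seg.q_end) - max(h.q_start, seg.q_start)
            if overlap > config.tile_max_overlap_bp:
                conflict = True
                break
        if not conflict:
            accepted.append(h)
    segments = [
        AnnotationSegment(
            q_start=h.q_start,
            q_end=h.q_end,
            category=(
                h.category
                or (catalog.category[h.subject_id] if catalog else "")
            ),
            subject_id=h.subject_id,
            s_start=h.s_start,
            s_end=h.s_end,
            strand=h.strand,
            score=h.score,
        )
        for h in accepted
    ]
    segments.sort(key=lambda s: (s.q_start, s.q_end, s.subject_id))
    return segments


def find_gaps(
    segments: Sequence[AnnotationSegment],
    read_len: int,
    config: Optional[PipelineConfig] = None,
) -> list[tuple[int, int]]:
    """Maximal uncovered read intervals strictly longer than 1 kbp."""
    config = config or PipelineConfig()
    events = sorted((s.q_start, s.q_end) for s in segments)
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for start, end in events:
        if start - cursor > config.unannotated_min_bp:
            gaps.append((cursor, start))
        cursor = max(cursor, end)
    if read_len - cursor > config.unannotated_min_bp:
        gaps.append((cursor, read_len))
    return gaps


def annotate_read(
    read: SeqRecord,
    index: SeedIndex,
    catalog: ReferenceCatalog,
    config: Optional[PipelineConfig] = None,
    scoring: Optional[ScoringScheme] = None,
) -> ReadAnnotation:
    """Full-catalog hit search + tiling + gap detection for one read."""
    config = config or PipelineConfig()
    scoring = scoring or ScoringScheme()
    hits = find_local_hits(
        read,
        index,
        scoring,
        min_identity=config.tdna_min_identity,
        max_evalue=config.tdna_max_evalue,
        min_aln_len=config.tdna_min_aln_len,
    )
    for h in hits:
        h.category = catalog.category[h.subject_id]
    segments = tile_annotation(hits, len(read.bases), config, catalog)
    if read.quals is not None:
        q = np.asarray(read.quals, dtype=float)
        for seg in segments:
            seg.mean_phred = float(q[seg.q_start : seg.q_end].mean())
    gaps = find_gaps(segments, len(read.bases), config)
    return ReadAnnotation(read.id, len(read.bases), segments, gaps)


def sliding_phred(
    read: SeqRecord,
    config: Optional[PipelineConfig] = None,
    allow_short: bool = False,
) -> QualityTrack:
    """Mean Phred in 200 nt windows advanced by 100 nt (anchored at 0)."""
    config = config or PipelineConfig()
    if read.quals is None:
        raise ValueError(f"read {read.id} has no qualities")
    w, step = config.qual_window_nt, config.qual_step_nt
    n = len(read.bases)
    q = np.asarray(read.quals, dtype=float)
    if n < w:
        if not allow_short:
            raise ValueError(
                f"read {read.id} shorter ({n}) than quality window ({w})"
            )
        return QualityTrack(read.id, w, step, [float(q.mean())])
    n_windows = (n - w) // step + 1
    cum = np.concatenate(([0.0], np.cumsum(q)))
    means = [
        float((cum[i * step + w] - cum[i * step]) / w) for i in range(n_windows)
    ]
    return QualityTrack(read.id, w, step, means)


@dataclass
class GapVerdict:
    gap: tuple[int, int]
    mean_phred: float
    verdict: str  # LOW_QUALITY | CANDIDATE_INVERTED_ARM | UNEXPLAINED


def flag_quality_drop(
    track: QualityTrack,
    annotation: ReadAnnotation,
    config: Optional[PipelineConfig] = None,
) -> list[GapVerdict]:
    """Label unannotated gaps by their window quality.

    A gap whose windows average <= ``low_q_threshold`` is LOW_QUALITY; if it
    is additionally flanked by T-DNA/BVB segments on both sides it is the
    signature of the second arm of an inverted T-DNA repeat and is labelled
    CANDIDATE_INVERTED_ARM.
    """
    config = config or PipelineConfig()
    if track.read_id != annotation.read_id:
        raise ValueError("track and annotation refer to different reads")
    out: list[GapVerdict] = []
    for gap in annotation.gaps:
        g0, g1 = gap
        vals = [
            m
            for i, m in enumerate(track.means)
            if min(g1, track.window_interval(i)[1]) - max(g0, track.window_interval(i)[0]) > 0
        ]
        mean_q = float(np.mean(vals)) if vals else float("nan")
        if vals and mean_q <= config.low_q_threshold:
            left = [s for s in annotation.segments if s.q_end <= g0 + config.tile_max_overlap_bp]
            right = [s for s in annotation.segments if s.q_start >= g1 - config.tile_max_overlap_bp]
            tdna_left = any(s.category in ("TDNA", "BVB") for s in left[-2:])
            tdna_right = any(s.category in ("TDNA", "BVB") for s in right[:2])
            verdict = (
                "CANDIDATE_INVERTED_ARM" if (tdna_left and tdna_right) else "LOW_QUALITY"
            )
        else:
            verdict = "UNEXPLAINED"
        out.append(GapVerdict(gap, mean_q, verdict))
    return out
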