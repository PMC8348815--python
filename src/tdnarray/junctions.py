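"""Junction analysis: filler DNA and microhomology at changeover points.

Every junction of a resolved structure is examined on a representative
supporting read.  The read sequence between the two assigned parts is the
candidate filler; its origin is sought with a cascaded search modelled on
junction analyses of integration loci: (1) ordinary local alignment
against the whole catalog, (2) a short-match search (permissive E <= 10,
word-size-5-class sensitivity via exact local DP) for fillers the seeded
search cannot see, and (3) the same short-match search after extending
the filler by 10 bases of context on each side, which rescues fillers
copied from sequence adjacent to the break.  Microhomology is the longest
exact suffix/prefix overlap of the two joined reference ends.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment import (
    Alignment,
    ScoringScheme,
    SeedIndex,
    _sw_full_kernel,
    encode,
    evalue,
    find_local_hits,
)
from .detection import PipelineConfig, ReferenceCatalog
from .loci import ChainUnit, InsertionStructure
from .records import LocalHit, SeqRecord, revcomp

#: inserts longer than this between two genomic units are structural
#: units in their own right, not junction filler
MAX_FILLER_SPAN = 2000


@dataclass
class JunctionWindow:
    junction_id: str
    seq: str  # read-derived window, canonical chain orientation
    left_origin: tuple  # (kind, subject_id, coordinate, strand)
    right_origin: tuple
    left_end: int  # window coord where the left assigned part ends
    right_start: int  # window coord where the right assigned part starts
    read_id: str = ""
    truncated: bool = False


@dataclass
class JunctionReport:
    junction_id: str
    left_origin: tuple
    right_origin: tuple
    filler_seq: str = ""
    filler_origin_hits: list = field(default_factory=list)
    microhomology_len: int = 0

    @property
    def filler_origin(self) -> str:
        if not self.filler_seq:
            return ""
        if not self.filler_origin_hits:
            return "UNKNOWN"
        return self.filler_origin_hits[0].category or self.filler_origin_hits[0].subject_id


# ---------------------------------------------------------------------------
# microhomology

def find_microhomology(left_seq: str, right_seq: str) -> int:
    """Longest exact suffix of ``left_seq`` equal to a prefix of ``right_seq``.

    The canonical microhomology-mediated end-joining overlap; 0 when the
    junction is blunt.
    """
    if not left_seq or not right_seq:
        raise ValueError("both junction sides must be non-empty")
    max_k = min(len(left_seq), len(right_seq))
    best = 0
    for k in range(1, max_k + 1):
        if left_seq[-k:] == right_seq[:k]:
            best = k
    return best


# ---------------------------------------------------------------------------
# junction windows

def _segment_matches_unit(seg, unit: ChainUnit, flipped: bool) -> bool:
    kind = seg.category if seg.category != "NUCLEAR" else "GENOMIC"
    if kind != unit.kind or seg.subject_id != unit.subject_id:
        return False
    orient = seg.strand
    if flipped:
        orient = "-" if orient == "+" else "+"
    if orient != unit.orientation:
        return False
    ov = min(seg.s_end, unit.s_end) - max(seg.s_start, unit.s_start)
    return ov > 0


def _junction_side_coord(unit: ChainUnit, side: str) -> int:
    """Reference coordinate of the unit edge facing the junction."""
    if side == "right":  # unit is left of the junction
        return unit.s_end if unit.orientation == "+" else unit.s_start
    return unit.s_start if unit.orientation == "+" else unit.s_end


def extract_junction_window(
    structure: InsertionStructure,
    junction: tuple[int, int],
    reads_by_id: dict,
    annotations_by_id: dict,
    config: Optional[PipelineConfig] = None,
) -> Optional[JunctionWindow]:
    """Read-derived sequence window around one junction of a structure.

    ``junction`` is a pair of chain indices (i, j), j > i: adjacent units
    for point junctions, or the two genomic units flanking a short
    filler-class insert.  The window carries ``window_bp/2`` of assigned
    context on each side plus everything between the assignments.  Returns
    None when no single read spans the junction.
    """
    config = config or PipelineConfig()
    i, j = junction
    if not (0 <= i < j < len(structure.chain)):
        raise IndexError(f"junction {junction} out of range")
    A, B = structure.chain[i], structure.chain[j]
    half = config.junction_window_bp // 2

    best: Optional[JunctionWindow] = None
    for rid in structure.supporting_reads:
        ann = annotations_by_id.get(rid)
        read = reads_by_id.get(rid)
        if ann is None or read is None:
            continue
        segs = sorted(ann.segments, key=lambda s: s.q_start)
        for flipped in (False, True):
            ordered = list(reversed(segs)) if flipped else segs
            for p_idx in range(len(ordered) - 1):
                p = ordered[p_idx]
                for q_idx in range(p_idx + 1, len(ordered)):
                    q = ordered[q_idx]
                    if not (
                        _segment_matches_unit(p, A, flipped)
                        and _segment_matches_unit(q, B, flipped)
                    ):
                        continue
                    # in read coordinates (pre-flip), p precedes q unless flipped
                    left_seg, right_seg = (q, p) if flipped else (p, q)
                    gap = right_seg.q_start - left_seg.q_end
                    if gap > MAX_FILLER_SPAN:
                        continue
                    lo = max(left_seg.q_start, left_seg.q_end - half)
                    hi = min(right_seg.q_end, right_seg.q_start + half)
                    if hi <= lo:
                        continue
                    seq = read.bases[lo:hi]
                    left_end = left_seg.q_end - lo
                    right_start = right_seg.q_start - lo
                    if flipped:
                        seq = revcomp(seq)
                        n = len(seq)
                        left_end, right_start = n - right_start, n - left_end
                    cand = JunctionWindow(
                        junction_id=f"{structure.locus_id}#J{i}-{j}",
                        seq=seq,
                        left_origin=(A.kind, A.subject_id, _junction_side_coord(A, "right"), A.orientation),
                        right_origin=(B.kind, B.subject_id, _junction_side_coord(B, "left"), B.orientation),
                        left_end=max(0, left_end),
                        right_start=min(len(seq), max(0, right_start)),
                        read_id=rid,
                        truncated=(left_end < half or (len(seq) - right_start) < half),
                    )
                    if best is None or (best.truncated and not cand.truncated):
                        best = cand
                break  # only the nearest matching pair for this p
    return best


def enumerate_junctions(structure: InsertionStructure) -> list[tuple[int, int]]:
    """Junction index pairs of a chain.

    Two genomic units separated only by short non-T-DNA material (an
    organellar capture or an unannotated stretch) form one composite
    genome::genome junction; everything else yields point junctions
    between consecutive units.
    """
    chain = structure.chain
    out: list[tuple[int, int]] = []
    k = 0
    while k < len(chain) - 1:
        if chain[k].kind == "GENOMIC":
            j = k + 1
            span = 0
            while (
                j < len(chain)
                and chain[j].kind not in ("GENOMIC", "TDNA", "BVB")
                and span + len(chain[j]) <= MAX_FILLER_SPAN
            ):
                span += len(chain[j])
                j += 1
            if j < len(chain) and chain[j].kind == "GENOMIC" and j > k + 1:
                out.append((k, j))
                k = j
                continue
        out.append((k, k + 1))
        k += 1
    return out


# ---------------------------------------------------------------------------
# filler classification

def _short_search(
    seq: str,
    catalog: ReferenceCatalog,
    scoring: ScoringScheme,
    max_evalue: float,
    db_len: int,
) -> list[LocalHit]:
    """Exhaustive short-match search (exact local DP on both strands)."""
    hits: list[LocalHit] = []
    q_codes = encode(seq)
    rq_codes = encode(revcomp(seq))
    for rec in catalog.records:
        s_codes = encode(rec.bases)
        for minus, wq in ((False, q_codes), (True, rq_codes)):
            res = _sw_full_kernel(
                wq, s_codes, scoring.match, scoring.mismatch,
                scoring.gap_open, scoring.gap_extend,
            )
            aln = Alignment(*[int(x) for x in res])
            if aln.score <= 0 or aln.aln_len < 1:
                continue
            E = evalue(aln.score, len(seq), db_len, scoring)
            if E > max_evalue:
                continue
            if minus:
                q_start, q_end = len(seq) - aln.q_end, len(seq) - aln.q_start
            else:
                q_start, q_end = aln.q_start, aln.q_end
            if q_end <= q_start:
                continue
            hits.append(
                LocalHit(
                    query_id="filler",
                    q_start=q_start,
                    q_end=q_end,
                    strand="-" if minus else "+",
                    subject_id=rec.id,
                    s_start=aln.s_start,
                    s_end=aln.s_end,
                    identity=aln.identity,
                    score=aln.score,
                    evalue=E,
                    aln_len=aln.aln_len,
                    category=catalog.category[rec.id],
                )
            )
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start))
    return hits


def classify_filler(
    window: JunctionWindow,
    catalog: ReferenceCatalog,
    index: SeedIndex,
    config: Optional[PipelineConfig] = None,
    scoring: Optional[ScoringScheme] = None,
) -> JunctionReport:
    """Filler extraction and origin assignment for one junction window.

    Stage 1 covers the window with ordinary local hits consistent with
    the junction's own left/right origins; the maximal unassigned middle
    part is the filler, whose origin is then sought with progressively
    more permissive searches.  The function is pure: re-running it on the
    same window reproduces the same report.
    """
    config = config or PipelineConfig()
    scoring = scoring or ScoringScheme()
    n = len(window.seq)
    report = JunctionReport(
        junction_id=window.junction_id,
        left_origin=window.left_origin,
        right_origin=window.right_origin,
    )

    # microhomology from the two joined reference ends; junction
    # coordinates estimated from noisy reads jitter by a few bases, so
    # scan a small offset neighbourhood and keep the best overlap
    mh_ctx = 40
    best_mh = 0
    for o1 in range(-3, 4):
        for o2 in range(-3, 4):
            left_ref = _origin_context(
                catalog, _shift_origin(window.left_origin, o1), "left", mh_ctx
            )
            right_ref = _origin_context(
                catalog, _shift_origin(window.right_origin, o2), "right", mh_ctx
            )
            if left_ref and right_ref:
                best_mh = max(best_mh, find_microhomology(left_ref, right_ref))
    report.microhomology_len = best_mh

    # stage 1: cover the window with hits consistent with the assignments
    covered = [(0, window.left_end), (window.right_start, n)]
    if n >= index.k:
        qrec = SeqRecord("junction_window", window.seq)
        hits = find_local_hits(
            qrec,
            index,
            scoring,
            min_identity=config.tdna_min_identity,
            max_evalue=config.junction_stage1_evalue,
            min_aln_len=20,
        )
        for h in hits:
            for origin in (window.left_origin, window.right_origin):
                if h.subject_id == origin[1] and abs_dist_to(origin[2], h) < 5_000:
                    covered.append((h.q_start, h.q_end))
    filler_lo, filler_hi = _max_uncovered_middle(covered, n)
    if filler_hi - filler_lo <= 0:
        return report
    report.filler_seq = window.seq[filler_lo:filler_hi]

    # stage 1 origin: ordinary hits over the filler interval
    stage1_origin = []
    if n >= index.k:
        for h in hits:
            ov = min(h.q_end, filler_hi) - max(h.q_start, filler_lo)
            if ov >= 0.5 * (filler_hi - filler_lo):
                stage1_origin.append(h)
    if stage1_origin:
        report.filler_origin_hits = stage1_origin
        return report

    # stage 2: short-match search of the bare filler
    db_len = index.total_len
    short = _short_search(report.filler_seq, catalog, scoring, config.filler_evalue, db_len)
    if short:
        report.filler_origin_hits = short
        return report

    # stage 3: extend by 10 bases of window context on each side and retry
    ext = config.filler_extension_bp
    lo3 = max(0, filler_lo - ext)
    hi3 = min(n, filler_hi + ext)
    extended = window.seq[lo3:hi3]
    short3 = _short_search(extended, catalog, scoring, config.filler_evalue, db_len)
    if short3:
        report.filler_origin_hits = short3
    return report


def abs_dist_to(coord: int, hit: LocalHit) -> int:
    if hit.s_start <= coord <= hit.s_end:
        return 0
    return min(abs(hit.s_start - coord), abs(hit.s_end - coord))


def _max_uncovered_middle(covered: list[tuple[int, int]], n: int) -> tuple[int, int]:
    """Largest gap strictly between covered prefix and covered suffix."""
    ivs = sorted((max(0, a), min(n, b)) for a, b in covered if b > a)
    if not ivs:
        return (0, 0)
    best = (0, 0)
    cursor = ivs[0][1]
    for a, b in ivs[1:]:
        if a > cursor and (a - cursor) > (best[1] - best[0]):
            best = (cursor, a)
        cursor = max(cursor, b)
    return best


def _shift_origin(origin: tuple, offset: int) -> tuple:
    kind, subject, coord, orient = origin
    return (kind, subject, max(0, coord + offset), orient)


def _origin_context(
    catalog: ReferenceCatalog, origin: tuple, side: str, ctx: int
) -> str:
    """Reference sequence running up to (side=left) or away from (right)
    the junction, in chain orientation."""
    kind, subject, coord, orient = origin
    if subject not in catalog:
        return ""
    seq = catalog.seq(subject)
    if side == "left":
        if orient == "+":
            return seq[max(0, coord - ctx) : coord]
        return revcomp(seq[coord : coord + ctx])
    if orient == "+":
        return seq[coord : coord + ctx]
    return revcomp(seq[max(0, coord - ctx) : coord])


def analyze_structure_junctions(
    structure: InsertionStructure,
    catalog: ReferenceCatalog,
    index: SeedIndex,
    reads_by_id: dict,
    annotations_by_id: dict,
    config: Optional[PipelineConfig] = None,
    scoring: Optional[ScoringScheme] = None,
) -> list[JunctionReport]:
    """All junction reports for one resolved structure."""
    config = config or PipelineConfig()
    reports = []
    for junction in enumerate_junctions(structure):
        window = extract_junction_window(
            structure, junction, reads_by_id, annotations_by_id, config
        )
        if window is None:
            continue
        reports.append(classify_filler(window, catalog, index, config, scoring))
    return reports
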