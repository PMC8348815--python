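"""Insertion-locus resolution: from tiled read annotations to structures.

Reads are clustered into loci by the reference projection of their
genome::insert changeover points (single linkage within a merge window).
Each read's annotation is converted to an ordered chain of units
(genomic / T-DNA / BVB / organellar / unannotated-low-quality); chains are
oriented so the left genomic flank runs forward, merged across reads by
unit-level overlap alignment, and reduced to one consensus chain per
locus.  Disagreements on a unit's extent resolve to the largest extent
supported by any single read, and an unannotated low-quality unit in one
read is rescued by a well-annotated unit at the same position in a read
of opposite direction (the inverted-repeat quality artifact).
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotation import ReadAnnotation
from .detection import CATEGORY_KIND, PipelineConfig, ReferenceCatalog
from .records import GenomicInterval

EDGE_TOL = 300  # read-edge proximity below which an alignment end is a clip
MIN_UNIT_BP = 150  # shorter tiled segments are treated as noise
MIN_ANCHOR_SEG = 200  # minimum genomic segment length to define a changeover
EXT_TOL = 60  # subject-extent tolerance when identifying the same unit
LOWQ_PHRED = 10.0  # segments at/below this mean Phred carry untrusted extents
GENOME_JOIN_TOL = 1000  # ref gap below which split genomic segments rejoin


@dataclass
class FlankAnchor:
    chrom: str
    position: int
    direction: str  # LEFT_OF_INSERT | RIGHT_OF_INSERT
    support: int
    ref_orient: str = "+"

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("anchor support must be >= 1")


@dataclass
class ChainUnit:
    kind: str  # GENOMIC | TDNA | BVB | FILLER | CPDNA | CHONDRIO | UNKNOWN_LOWQ
    subject_id: str
    s_start: int
    s_end: int
    orientation: str
    border_left: str = "NA"
    border_right: str = "NA"
    support: int = 1

    def __len__(self) -> int:
        return self.s_end - self.s_start


@dataclass
class InsertionStructure:
    locus_id: str
    left_flank: Optional[FlankAnchor]
    right_flank: Optional[FlankAnchor]
    chain: list
    supporting_reads: list
    target_site_deletion_bp: int = 0
    flags: list = field(default_factory=list)
    internal_junctions: list = field(default_factory=list)  # e.g. "RB_RB"
    candidate_chains: list = field(default_factory=list)


@dataclass
class EventCall:
    locus_id: str
    event_type: str
    partners: list
    notes: str = ""


@dataclass
class ZygosityEstimate:
    locus_id: str
    wt_allele_read_fraction: float
    call: str  # HOMOZYGOUS | SEGREGATING | UNDETERMINED


# ---------------------------------------------------------------------------
# per-read unit chains

@dataclass
class RawUnit:
    kind: str
    subject: str
    s_start: int
    s_end: int
    orient: str
    read_id: str
    reliable_left: bool = True  # subject low-coordinate side trustworthy
    reliable_right: bool = True
    flipped: bool = False
    low_quality: bool = False  # segment mean Phred at/below the low-q threshold
    prev_kind: Optional[str] = None  # chain-space neighbours on this read
    next_kind: Optional[str] = None

    @property
    def length(self) -> int:
        return self.s_end - self.s_start


def read_chain(ann: ReadAnnotation) -> list[RawUnit]:
    """Ordered unit chain of one read, in read orientation.

    Adjacent same-subject segments that continue each other on the
    reference are rejoined (tiling can split one unit at an error patch);
    unannotated gaps become UNKNOWN_LOWQ units.
    """
    items: list[tuple[int, int, RawUnit]] = []
    for seg in ann.segments:
        if seg.q_end - seg.q_start < MIN_UNIT_BP:
            continue
        items.append(
            (
                seg.q_start,
                seg.q_end,
                RawUnit(
                    kind=CATEGORY_KIND.get(seg.category, seg.category),
                    subject=seg.subject_id,
                    s_start=seg.s_start,
                    s_end=seg.s_end,
                    orient=seg.strand,
                    read_id=ann.read_id,
                    low_quality=(
                        seg.mean_phred is not None and seg.mean_phred <= LOWQ_PHRED
                    ),
                ),
            )
        )
    for g0, g1 in ann.gaps:
        items.append(
            (
                g0,
                g1,
                RawUnit("UNKNOWN_LOWQ", "", 0, g1 - g0, "+", ann.read_id),
            )
        )
    items.sort(key=lambda t: (t[0], t[1]))

    # rejoin split units: same subject, orient, reference-contiguous
    merged: list[tuple[int, int, RawUnit]] = []
    for q0, q1, u in items:
        if merged:
            p0, p1, prev = merged[-1]
            if (
                u.kind == prev.kind
                and u.kind != "UNKNOWN_LOWQ"
                and u.subject == prev.subject
                and u.orient == prev.orient
                and q0 - p1 < GENOME_JOIN_TOL
            ):
                ref_gap = (
                    u.s_start - prev.s_end if u.orient == "+" else prev.s_start - u.s_end
                )
                if -GENOME_JOIN_TOL < ref_gap < GENOME_JOIN_TOL:
                    prev.s_start = min(prev.s_start, u.s_start)
                    prev.s_end = max(prev.s_end, u.s_end)
                    prev.low_quality = prev.low_quality or u.low_quality
                    merged[-1] = (p0, max(p1, q1), prev)
                    continue
        merged.append((q0, q1, u))

    chain: list[RawUnit] = []
    for idx, (q0, q1, u) in enumerate(merged):
        at_read_start = q0 <= EDGE_TOL
        at_read_end = q1 >= ann.read_len - EDGE_TOL
        # the read-left edge of the alignment maps to the subject low side
    # for + units and the high side for - units
        left_clip = idx == 0 and at_read_start
        right_clip = idx == len(merged) - 1 and at_read_end
        if u.orient == "+":
            u.reliable_left = not left_clip
            u.reliable_right = not right_clip
        else:
            u.reliable_left = not right_clip
            u.reliable_right = not left_clip
        u.prev_kind = merged[idx - 1][2].kind if idx > 0 else None
        u.next_kind = merged[idx + 1][2].kind if idx < len(merged) - 1 else None
        chain.append(u)
    return chain


def canonicalize(chain: list[RawUnit]) -> list[RawUnit]:
    """Flip the chain if its first genomic unit runs backwards."""
    first_gen = next((u for u in chain if u.kind == "GENOMIC"), None)
    if first_gen is None or first_gen.orient == "+":
        return chain
    return flip_chain(chain)


def flip_chain(chain: list[RawUnit]) -> list[RawUnit]:
    out = []
    for u in reversed(chain):
        out.append(
            RawUnit(
                kind=u.kind,
                subject=u.subject,
                s_start=u.s_start,
                s_end=u.s_end,
                orient="-" if u.orient == "+" else "+",
                read_id=u.read_id,
                reliable_left=u.reliable_left,
                reliable_right=u.reliable_right,
                flipped=not u.flipped,
                low_quality=u.low_quality,
                prev_kind=u.next_kind,
                next_kind=u.prev_kind,
            )
        )
    return out


# ---------------------------------------------------------------------------
# locus clustering

@dataclass
class Anchor:
    chrom: str
    position: int
    direction: str
    read_id: str


@dataclass
class LocusGroup:
    annotations: list
    anchors: list


def _read_anchors(ann: ReadAnnotation, config: PipelineConfig) -> list[Anchor]:
    chain = []
    for seg in ann.segments:
        if seg.q_end - seg.q_start < MIN_UNIT_BP:
            continue
        chain.append(seg)
    chain.sort(key=lambda s: s.q_start)
    anchors: list[Anchor] = []
    for a, b in zip(chain, chain[1:]):
        a_gen = a.category == "NUCLEAR"
        b_gen = b.category == "NUCLEAR"
        if a_gen and b_gen:
            # genomic continuation is not a changeover
            if (
                a.subject_id == b.subject_id
                and a.strand == b.strand
                and (
                    abs(b.s_start - a.s_end) < GENOME_JOIN_TOL
                    if a.strand == "+"
                    else abs(a.s_start - b.s_end) < GENOME_JOIN_TOL
                )
            ):
                continue
        if a_gen and a.q_end - a.q_start >= MIN_ANCHOR_SEG:
            pos = a.s_end if a.strand == "+" else a.s_start
            direction = "LEFT_OF_INSERT" if a.strand == "+" else "RIGHT_OF_INSERT"
            anchors.append(Anchor(a.subject_id, pos, direction, ann.read_id))
        if b_gen and b.q_end - b.q_start >= MIN_ANCHOR_SEG:
            pos = b.s_start if b.strand == "+" else b.s_end
            direction = "RIGHT_OF_INSERT" if b.strand == "+" else "LEFT_OF_INSERT"
            anchors.append(Anchor(b.subject_id, pos, direction, ann.read_id))
    return anchors


def cluster_loci(
    annotations: Sequence[ReadAnnotation],
    config: Optional[PipelineConfig] = None,
) -> tuple[list[LocusGroup], list[ReadAnnotation]]:
    """Group reads into loci by changeover proximity (single linkage).

    Returns (locus groups, unanchored annotations).  Two reads share a
    locus iff changeover projections on the same chromosome lie within
    ``merge_window``; closure follows shared reads, so the two flanks of
    one insertion (or translocation) form one locus.
    """
    config = config or PipelineConfig()
    all_anchors: list[Anchor] = []
    per_read: dict[str, list[Anchor]] = {}
    unanchored: list[ReadAnnotation] = []
    for ann in annotations:
        anchors = _read_anchors(ann, config)
        if not anchors:
            unanchored.append(ann)
            continue
        per_read[ann.read_id] = anchors
        all_anchors.extend(anchors)

    # positional clustering per chromosome
    all_anchors.sort(key=lambda a: (a.chrom, a.position))
    cluster_of: dict[int, int] = {}
    n_clusters = 0
    prev = None
    for anc in all_anchors:
        if (
            prev is not None
            and anc.chrom == prev.chrom
            and anc.position - prev.position <= config.merge_window
        ):
            cluster_of[id(anc)] = n_clusters - 1
        else:
            cluster_of[id(anc)] = n_clusters
            n_clusters += 1
        prev = anc

    # union-find over clusters, joined through shared reads
    parent = list(range(n_clusters))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for read_id, anchors in per_read.items():
        ids = [cluster_of[id(a)] for a in anchors]
        for other in ids[1:]:
            union(ids[0], other)

    groups: dict[int, LocusGroup] = {}
    ann_by_id = {a.read_id: a for a in annotations}
    seen_reads: dict[int, set] = {}
    for read_id, anchors in per_read.items():
        root = find(cluster_of[id(anchors[0])])
        grp = groups.setdefault(root, LocusGroup([], []))
        reads_seen = seen_reads.setdefault(root, set())
        if read_id not in reads_seen:
            grp.annotations.append(ann_by_id[read_id])
            reads_seen.add(read_id)
        grp.anchors.extend(anchors)
    ordered = sorted(
        groups.values(),
        key=lambda g: (g.anchors[0].chrom, min(a.position for a in g.anchors)),
    )
    return ordered, unanchored


# ---------------------------------------------------------------------------
# consensus structure

@dataclass
class _ConsensusUnit:
    kind: str
    subject: str
    orient: str
    members: list  # RawUnits

    def add(self, u: RawUnit) -> None:
        if self.kind == "UNKNOWN_LOWQ" and u.kind != "UNKNOWN_LOWQ":
            # inverted-repeat rescue: a well-annotated unit replaces the
            # low-quality placeholder
            self.kind = u.kind
            self.subject = u.subject
            self.orient = u.orient
            self.members = [m for m in self.members if m.kind != "UNKNOWN_LOWQ"] + [u]
        else:
            self.members.append(u)

    def solid_members(self) -> list:
        return [m for m in self.members if m.kind != "UNKNOWN_LOWQ"]

    def resolve(self) -> ChainUnit:
        solid = self.solid_members()
        if not solid:
            lengths = [m.length for m in self.members]
            return ChainUnit(
                "UNKNOWN_LOWQ", "", 0, max(lengths), "+", support=len(self.members)
            )
        # largest extent supported by any single read, per side; good-quality
        # reads take precedence over degraded-arm observations
        pool = [m for m in solid if not m.low_quality] or solid
        starts = [m.s_start for m in pool if m.reliable_left]
        ends = [m.s_end for m in pool if m.reliable_right]
        s_start = min(starts) if starts else min(m.s_start for m in pool)
        s_end = max(ends) if ends else max(m.s_end for m in pool)
        return ChainUnit(
            self.kind, self.subject, s_start, s_end, self.orient, support=len(solid)
        )


def _units_match(a: _ConsensusUnit, b: RawUnit) -> Optional[str]:
    """'strict', 'wildcard' or None (conflict) for aligning b onto a."""
    if a.kind == "UNKNOWN_LOWQ" or b.kind == "UNKNOWN_LOWQ":
        other_kind = b.kind if a.kind == "UNKNOWN_LOWQ" else a.kind
        if other_kind in ("GENOMIC",):
            return None  # a low-quality stretch never replaces a genomic flank
        return "wildcard"
    if a.kind != b.kind or a.subject != b.subject or a.orient != b.orient:
        return None
    sm = a.solid_members()
    a_lo = min(m.s_start for m in sm)
    a_hi = max(m.s_end for m in sm)
    ov = min(a_hi, b.s_end) - max(a_lo, b.s_start)
    if a.kind == "GENOMIC":
        # genuine flank-mates share kilobases around the junction; a mere
        # "nearby" interval may be the opposite flank across a small
        # target-site deletion and must not match
        return "strict" if ov > 50 else None
    if ov <= 0:
        return None
    # extents measured on low-quality stretches (the degraded second arm of
    # an inverted repeat) are too ragged to identify a unit; only
    # good-quality reads vote on identity
    good = [m for m in sm if not m.low_quality]
    if b.low_quality or not good:
        return "strict"
    checks = []
    starts = [m.s_start for m in good if m.reliable_left]
    ends = [m.s_end for m in good if m.reliable_right]
    if starts and b.reliable_left:
        checks.append(abs(statistics.median(starts) - b.s_start) <= EXT_TOL)
    if ends and b.reliable_right:
        checks.append(abs(statistics.median(ends) - b.s_end) <= EXT_TOL)
    if not checks:
        return "strict"  # only overlap evidence available (clipped unit)
    return "strict" if any(checks) else None


def _align_chain(
    consensus: list[_ConsensusUnit], chain: list[RawUnit]
) -> Optional[tuple[int, float]]:
    """Best offset aligning ``chain`` onto ``consensus``.

    Returns (offset, score) or None; ambiguous equal-score offsets return
    None.  Offset o places chain[j] at consensus position o + j.
    """
    best: Optional[tuple[int, float]] = None
    tie = False
    for offset in range(-len(chain) + 1, len(consensus)):
        score = 0.0
        valid = True
        overlap = 0
        for j, u in enumerate(chain):
            i = offset + j
            if i < 0 or i >= len(consensus):
                continue
            overlap += 1
            m = _units_match(consensus[i], u)
            if m is None:
                valid = False
                break
            score += 1.0 if m == "strict" else 0.25
        if not valid or overlap == 0 or score <= 0:
            continue
        if best is None or score > best[1]:
            best = (offset, score)
            tie = False
        elif score == best[1]:
            tie = True
    if best is None or tie:
        return None
    return best


def _any_offset_exists(consensus: list[_ConsensusUnit], chain: list[RawUnit]) -> bool:
    for cand in (chain, flip_chain(chain)):
        for offset in range(-len(cand) + 1, len(consensus)):
            valid = True
            overlap = 0
            for j, u in enumerate(cand):
                i = offset + j
                if i < 0 or i >= len(consensus):
                    continue
                overlap += 1
                if _units_match(consensus[i], u) is None:
                    valid = False
                    break
            if valid and overlap:
                return True
    return False


def merge_chains(
    chains: list[list[RawUnit]],
) -> tuple[list[_ConsensusUnit], list[list[RawUnit]], list[list[RawUnit]]]:
    """Greedy unit-level assembly of read chains into one consensus.

    Returns (consensus, incompatible chains, placement-ambiguous chains).
    Chains are taken longest first; each subsequent chain is tried in both
    orientations and merged at its best unambiguous offset.  Chains
    consistent with the consensus at several equally good placements add
    no structural information and are set aside; chains with no valid
    placement at all contradict the consensus.
    """
    ordered = sorted(
        chains,
        key=lambda ch: (-len(ch), -sum(u.length for u in ch)),
    )
    backbone = ordered[0]
    consensus = [
        _ConsensusUnit(u.kind, u.subject, u.orient, [u]) for u in backbone
    ]
    pending = list(ordered[1:])
    progress = True
    while pending and progress:
        progress = False
        still: list[list[RawUnit]] = []
        for ch in pending:
            options = []
            for cand in (ch, flip_chain(ch)):
                res = _align_chain(consensus, cand)
                if res is not None:
                    options.append((res[1], res[0], cand))
            if not options:
                still.append(ch)
                continue
            options.sort(key=lambda t: -t[0])
            if len(options) == 2 and options[0][0] == options[1][0]:
                still.append(ch)  # orientation-ambiguous, retry later
                continue
            _, offset, cand = options[0]
            # prepend positions hanging off the left; the insertion shifts
            # all existing consensus indices right by the head length, so
            # the remaining units land at index -offset
            if offset < 0:
                head = [
                    _ConsensusUnit(u.kind, u.subject, u.orient, [u])
                    for u in cand[: -offset]
                ]
                consensus[:0] = head
                cand = cand[-offset:]
                offset = -offset
            for j, u in enumerate(cand):
                i = offset + j
                if i < len(consensus):
                    consensus[i].add(u)
                else:
                    consensus.append(_ConsensusUnit(u.kind, u.subject, u.orient, [u]))
            progress = True
        pending = still
        # collapse offset-drift duplicates before the next pass: pending
        # chains often tie against a consensus that still carries them
        if _compact(consensus):
            progress = True
    incompatible = [ch for ch in pending if not _any_offset_exists(consensus, ch)]
    ambiguous = [ch for ch in pending if _any_offset_exists(consensus, ch)]
    return consensus, incompatible, ambiguous


def _compact(consensus: list[_ConsensusUnit]) -> bool:
    """Collapse adjacent duplicate consensus units caused by offset drift.

    Two neighbouring positions describing the same unit (same kind,
    subject, orientation, compatible extents) are merged -- unless some
    read shows them as two distinct units in one chain, which protects
    genuine tandem copies.  Returns True when anything was collapsed.
    """
    any_change = False
    changed = True
    while changed:
        changed = False
        for i in range(len(consensus) - 1):
            a, b = consensus[i], consensus[i + 1]
            if a.kind == "UNKNOWN_LOWQ" or b.kind == "UNKNOWN_LOWQ":
                continue
            if (a.kind, a.subject, a.orient) != (b.kind, b.subject, b.orient):
                continue
            reads_a = {m.read_id for m in a.members}
            reads_b = {m.read_id for m in b.members}
            if reads_a & reads_b:
                continue
            if all(_units_match(a, m) == "strict" for m in b.solid_members()):
                a.members.extend(b.members)
                del consensus[i + 1]
                changed = True
                any_change = True
                break
    return any_change


def _flank_positions(cu: _ConsensusUnit, side: str) -> list[int]:
    """Junction-coordinate observations from a flank consensus unit.

    ``side`` is 'right' for the left flank (junction at its chain-right
    edge) and 'left' for the right flank.
    """
    primary: list[int] = []
    fallback: list[int] = []
    for m in cu.solid_members():
        if side == "right":
            neighbour = m.next_kind
            reliable = m.reliable_right if m.orient == "+" else m.reliable_left
            pos = m.s_end if m.orient == "+" else m.s_start
        else:
            neighbour = m.prev_kind
            reliable = m.reliable_left if m.orient == "+" else m.reliable_right
            pos = m.s_start if m.orient == "+" else m.s_end
        # only reads that actually reach the changeover observe the
        # junction position; any surviving neighbour implies a genuine
        # discontinuity (continuous genomic pieces were rejoined earlier),
        # but a low-quality gap neighbour is a softer observation
        if not reliable or neighbour is None:
            continue
        if neighbour == "UNKNOWN_LOWQ":
            fallback.append(pos)
        else:
            primary.append(pos)
    return primary or fallback


def build_structure(
    group: LocusGroup,
    catalog: ReferenceCatalog,
    config: Optional[PipelineConfig] = None,
) -> InsertionStructure:
    """Consensus insertion structure of one locus group."""
    config = config or PipelineConfig()
    chains = []
    for ann in group.annotations:
        ch = canonicalize(read_chain(ann))
        if ch:
            chains.append(ch)
    if not chains:
        raise ValueError("locus group has no usable reads")
    consensus, incompatible, ambiguous = merge_chains(chains)

    # strip dangling low-quality units at the ends (no structural meaning)
    while consensus and consensus[0].kind == "UNKNOWN_LOWQ":
        consensus.pop(0)
    while consensus and consensus[-1].kind == "UNKNOWN_LOWQ":
        consensus.pop()

    units = [cu.resolve() for cu in consensus]
    flags: list[str] = []
    read_ids = sorted({ann.read_id for ann in group.annotations})
    if len(read_ids) == 1:
        flags.append("LOW_SUPPORT")
    if len(incompatible) > max(1, 0.2 * len(chains)):
        flags.append("UNRESOLVED")

    left_flank = right_flank = None
    if units and units[0].kind == "GENOMIC":
        obs = _flank_positions(consensus[0], "right")
        if obs:
            pos = int(statistics.median(obs))
            left_flank = FlankAnchor(
                units[0].subject_id,
                pos,
                "LEFT_OF_INSERT" if units[0].orientation == "+" else "RIGHT_OF_INSERT",
                support=len(obs),
                ref_orient=units[0].orientation,
            )
    else:
        flags.append("NO_LEFT_FLANK")
    if len(units) > 1 and units[-1].kind == "GENOMIC":
        obs = _flank_positions(consensus[-1], "left")
        if obs:
            pos = int(statistics.median(obs))
            right_flank = FlankAnchor(
                units[-1].subject_id,
                pos,
                "RIGHT_OF_INSERT" if units[-1].orientation == "+" else "LEFT_OF_INSERT",
                support=len(obs),
                ref_orient=units[-1].orientation,
            )
    elif "NO_LEFT_FLANK" not in flags:
        flags.append("NO_RIGHT_FLANK")

    target_deletion = 0
    if (
        left_flank
        and right_flank
        and left_flank.chrom == right_flank.chrom
        and left_flank.ref_orient == "+"
        and right_flank.ref_orient == "+"
    ):
        target_deletion = max(0, right_flank.position - left_flank.position)

    locus_parts = []
    for fl in (left_flank, right_flank):
        if fl:
            locus_parts.append(f"{fl.chrom}:{fl.position}")
    locus_id = "--".join(locus_parts) or f"unanchored:{read_ids[0]}"

    structure = InsertionStructure(
        locus_id=locus_id,
        left_flank=left_flank,
        right_flank=right_flank,
        chain=units,
        supporting_reads=read_ids,
        target_site_deletion_bp=target_deletion,
        flags=flags,
        candidate_chains=[[u for u in ch] for ch in incompatible],
    )
    border_status(structure.chain, catalog, config)
    structure.internal_junctions = _internal_junctions(structure.chain)
    return structure


# ---------------------------------------------------------------------------
# borders

def border_status(
    chain: Sequence[ChainUnit],
    catalog: ReferenceCatalog,
    config: Optional[PipelineConfig] = None,
) -> None:
    """Annotate LB/RB status of every T-DNA unit edge in place.

    LB_INTACT iff the unit extends to within ``lb_slack`` of the start of
    the 25 bp LB repeat (vector position 1); RB_INTACT analogously at the
    vector's far end.  Edges internal to the array are INTERNAL.
    """
    config = config or PipelineConfig()
    tdna_units = [u for u in chain if u.kind == "TDNA"]
    if not tdna_units:
        return
    for idx, u in enumerate(chain):
        if u.kind != "TDNA":
            continue
        vec_len = catalog.length(u.subject_id) if u.subject_id in catalog else None
        lb_state = "LB_INTACT" if u.s_start <= config.lb_slack else "LB_TRUNCATED"
        if vec_len is None:
            rb_state = "RB_TRUNCATED"
        else:
            rb_state = (
                "RB_INTACT" if u.s_end >= vec_len - config.lb_slack else "RB_TRUNCATED"
            )
        if u.orientation == "+":
            u.border_left, u.border_right = lb_state, rb_state
        else:
            u.border_left, u.border_right = rb_state, lb_state
        # edges facing non-genomic neighbours are internal to the array
        if idx > 0 and chain[idx - 1].kind not in ("GENOMIC",):
            u.border_left = "INTERNAL"
        if idx < len(chain) - 1 and chain[idx + 1].kind not in ("GENOMIC",):
            u.border_right = "INTERNAL"


def _internal_junctions(chain: Sequence[ChainUnit]) -> list[str]:
    """Classify unit::unit junctions inside the array (RB::RB etc.)."""
    out = []
    non_gen = [u for u in chain if u.kind not in ("GENOMIC", "UNKNOWN_LOWQ")]
    for a, b in zip(non_gen, non_gen[1:]):
        if a.kind != "TDNA" or b.kind != "TDNA":
            out.append(f"{a.kind}_{b.kind}")
            continue
        # the RB-proximal end of a unit is its high-vector-coordinate end
        a_rb_facing = a.orientation == "+"
        b_rb_facing = b.orientation == "-"
        if a_rb_facing and b_rb_facing:
            out.append("RB_RB")
        elif not a_rb_facing and not b_rb_facing:
            out.append("LB_LB")
        else:
            out.append("RB_LB")
    return out


# ---------------------------------------------------------------------------
# event classification

def classify_event(
    structures: Sequence[InsertionStructure],
    tdna_free_fusions: Sequence[InsertionStructure] = (),
    catalog: Optional[ReferenceCatalog] = None,
    cnv_calls: Sequence = (),
    pair_tolerance: int = 50_000,
) -> list[EventCall]:
    """Genome-level event calls for resolved structures.

    T-DNA-free fusion structures (from flank recruitment) are passed
    separately; reciprocal translocation fusions exchanging the same
    chromosome arms are cross-referenced in the notes.
    """
    calls: list[EventCall] = []

    def non_genomic(st: InsertionStructure) -> list[ChainUnit]:
        return [u for u in st.chain if u.kind not in ("GENOMIC",)]

    for st in structures:
        lf, rf = st.left_flank, st.right_flank
        units = non_genomic(st)
        solid = [u for u in units if u.kind != "UNKNOWN_LOWQ"]
        partners: list = []
        if lf and rf and lf.chrom != rf.chrom:
            etype = "TRANSLOCATION_FUSION"
            partners = [
                (lf.chrom, lf.position, lf.direction),
                (rf.chrom, rf.position, rf.direction),
            ]
        elif lf and rf and rf.ref_orient == "-" and lf.ref_orient == "+":
            etype = "INVERTED_DUPLICATION"
            partners = [(lf.chrom, lf.position, lf.direction), (rf.chrom, rf.position, rf.direction)]
        elif len(solid) == 1 and solid[0].kind == "TDNA" and len(units) == 1:
            etype = "CANONICAL_INSERTION"
            if lf:
                partners = [(lf.chrom, lf.position, lf.direction)]
        elif len(units) >= 2:
            etype = "COMPLEX_ARRAY"
            if lf:
                partners = [(lf.chrom, lf.position, lf.direction)]
        elif units and all(u.kind in ("CPDNA", "CHONDRIO") for u in units):
            etype = "CPDNA_INSERTION"
            if lf and rf:
                partners = [
                    (lf.chrom, lf.position, lf.direction),
                    (rf.chrom, rf.position, rf.direction),
                ]
        elif not units and lf and rf:
            etype = "TDNA_FREE_FUSION"
            partners = [
                (lf.chrom, lf.position, lf.direction),
                (rf.chrom, rf.position, rf.direction),
            ]
        else:
            etype = "CANONICAL_INSERTION" if solid else "COMPLEX_ARRAY"
            if lf:
                partners = [(lf.chrom, lf.position, lf.direction)]
        notes = ""
        if etype == "INVERTED_DUPLICATION" and cnv_calls:
            near_gain = [
                c
                for c in cnv_calls
                if c.direction == "GAIN"
                and lf
                and c.interval.chrom == lf.chrom
                and c.interval.start - 25_000 <= lf.position <= c.interval.end + 25_000
            ]
            notes = (
                "coverage gain supports duplication"
                if near_gain
                else "no coverage gain found near anchor"
            )
        calls.append(EventCall(st.locus_id, etype, partners, notes))
        if etype != "CPDNA_INSERTION" and any(u.kind == "CPDNA" for u in st.chain):
            calls.append(
                EventCall(st.locus_id, "CPDNA_INSERTION", partners, "plastome-derived unit in chain")
            )

    for st in tdna_free_fusions:
        lf, rf = st.left_flank, st.right_flank
        if lf is None or rf is None:
            continue
        calls.append(
            EventCall(
                st.locus_id,
                "TDNA_FREE_FUSION",
                [
                    (lf.chrom, lf.position, lf.direction),
                    (rf.chrom, rf.position, rf.direction),
                ],
            )
        )

    # reciprocity: pair fusions exchanging the same chromosome arms
    fusionlike = [
        c for c in calls if c.event_type in ("TRANSLOCATION_FUSION", "TDNA_FREE_FUSION")
    ]
    for i, c1 in enumerate(fusionlike):
        for c2 in fusionlike[i + 1 :]:
            ch1 = {p[0] for p in c1.partners}
            ch2 = {p[0] for p in c2.partners}
            if ch1 != ch2 or len(ch1) != 2:
                continue
            matched = True
            for chrom, pos, _d in c1.partners:
                close = [
                    p for p in c2.partners if p[0] == chrom and abs(p[1] - pos) <= pair_tolerance
                ]
                if not close:
                    matched = False
            if matched:
                tag1 = f"reciprocal_with={c2.locus_id}"
                tag2 = f"reciprocal_with={c1.locus_id}"
                c1.notes = f"{c1.notes}; {tag1}".strip("; ")
                c2.notes = f"{c2.notes}; {tag2}".strip("; ")
    return calls


# ---------------------------------------------------------------------------
# zygosity

def estimate_zygosity(
    locus_id: str,
    wt_spanning: float,
    insert_supporting: float,
    config: Optional[PipelineConfig] = None,
) -> ZygosityEstimate:
    """Zygosity from spanning-read counts in a selected T2 pool.

    With full selection, 2/3 of chromosomes carry the insertion, so a
    segregating locus shows a wild-type read fraction near 1/3.
    """
    config = config or PipelineConfig()
    total = wt_spanning + insert_supporting
    if total < config.min_depth:
        return ZygosityEstimate(locus_id, float("nan"), "UNDETERMINED")
    frac = wt_spanning / total
    if frac < 0.15:
        call = "HOMOZYGOUS"
    elif frac <= 0.60:
        call = "SEGREGATING"
    else:
        call = "UNDETERMINED"
    return ZygosityEstimate(locus_id, frac, call)
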