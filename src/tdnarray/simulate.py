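"""Synthetic genomes with planted T-DNA integration events and ONT-like reads.

The generator produces a small wild-type genome (five 150 kbp chromosomes,
a 20 kbp plastome, a 10 kbp chondrome) plus a binary-vector T-DNA record
with 25 bp left/right border repeats at its ends, plants structured
integration events (arrays, reciprocal translocations, inverted
duplications, organellar fillers, T-DNA-free fusions) while recording
exact truth, and simulates long reads with i.i.d. per-base errors, a
log-normal length distribution, and the characteristic quality collapse
over the second arm of an inverted repeat.

Reads are drawn from the mutant and wild-type haplotypes according to the
segregation expectation of a selected T2 pool (2/3 of chromosomes carry
the insertion, i.e. wild-type allele fraction 1/3).

Everything is deterministic under ``rng_seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detection import ReferenceCatalog
from .records import SeqRecord, revcomp

TDNA_ID = "pTD1"
BVB_ID = "pTD1_bvb"
BORDER_LEN = 25


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    rng_seed: int = 0
    chrom_sizes: dict = field(
        default_factory=lambda: {f"chr{i}": 150_000 for i in range(1, 6)}
    )
    plastome_size: int = 20_000
    chondrome_size: int = 10_000
    tdna_size: int = 6_000
    bvb_size: int = 3_000
    read_median: int = 15_000
    read_sigma: float = 0.6  # sigma of log read length
    read_min: int = 1_000
    read_max: int = 100_000
    mismatch_rate: float = 0.04
    insertion_rate: float = 0.03
    deletion_rate: float = 0.04
    phred_mean: float = 13.0
    phred_sd: float = 3.0
    inverted_arm_quality_drop: bool = True
    low_phred_mean: float = 7.0
    low_phred_sd: float = 1.5
    low_arm_sub_factor: float = 3.0
    depth: float = 30.0
    wt_allele_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.insertion_rate, self.deletion_rate):
            if not (0.0 <= r < 1.0):
                raise SimulationError("error rates must be in [0,1)")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if not (0.0 <= self.wt_allele_fraction <= 1.0):
            raise SimulationError("wt_allele_fraction must be in [0,1]")


@dataclass
class ArrayUnit:
    """One unit of a planted insert, in catalog-subject coordinates."""

    subject: str
    s_start: int
    s_end: int
    orient: str  # +/-
    kind: str = ""  # filled from the catalog category

    def __post_init__(self) -> None:
        if not self.s_start < self.s_end:
            raise SimulationError("unit s_start must be < s_end")
        if self.orient not in "+-":
            raise SimulationError("unit orient must be + or -")


@dataclass
class EventSpec:
    kind: str  # TDNA_ARRAY | TRANSLOCATION_PAIR | INVERTED_DUPLICATION |
    #           CPDNA_FILLER_JUNCTION | TDNA_FREE_FUSION
    chrom: str = ""
    position: int = 0
    units: list = field(default_factory=list)
    target_deletion: int = 0
    microhomology: int = 0
    filler_len: int = 0
    filler_origin: str = ""  # subject id, e.g. "plastome"
    filler_src: int = 0
    chrom2: str = ""
    position2: int = 0
    microhomology2: int = 0
    dup_start: int = 0
    dup_end: int = 0
    name: str = ""


@dataclass
class SourceSegment:
    """Provenance of one piece of a mutant chromosome."""

    start: int  # mutant chromosome coords
    end: int
    kind: str  # GENOMIC | TDNA | BVB | CPDNA | CHONDRIO | FILLER
    source_id: str
    s_start: int
    s_end: int
    orient: str


@dataclass
class JunctionTruth:
    left: tuple  # (kind, source_id, coordinate, orient) at the changeover
    right: tuple
    filler_seq: str = ""
    filler_origin: str = ""
    filler_src: int = 0
    microhomology: int = 0


@dataclass
class EventTruth:
    event_id: str
    kind: str
    spec: EventSpec
    chain: list  # list[ArrayUnit] of non-genomic units, locus orientation
    junctions: list  # list[JunctionTruth]
    anchors: list  # list[(chrom, position, direction)] genome::insert changeovers
    mutant_chrom: str = ""


@dataclass
class ReadTruth:
    read_id: str
    haplotype: str  # "mutant" | "wildtype"
    chrom: str
    start: int
    end: int
    strand: str
    segments: list = field(default_factory=list)  # SourceSegment slices (template space)
    low_quality_arm: Optional[tuple] = None  # template-space interval


@dataclass
class TruthSet:
    events: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)  # mut chrom -> [SourceSegment]
    ir_arms: dict = field(default_factory=dict)  # mut chrom -> [(a1s,a1e,a2s,a2e)]
    reads: dict = field(default_factory=dict)  # read_id -> ReadTruth


# ---------------------------------------------------------------------------
# genome construction

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_genome(
    config: Optional[SimulationConfig] = None,
) -> tuple[dict[str, str], ReferenceCatalog]:
    """Wild-type genome plus the full annotation catalog.

    The T-DNA record carries its LB repeat at (0-based) positions [0,25)
    and its RB repeat at the last 25 positions, matching the binary-vector
    coordinate convention in which position 1 is the left end of LB.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    genome = {c: _random_seq(rng, n) for c, n in config.chrom_sizes.items()}
    plastome = _random_seq(rng, config.plastome_size)
    chondrome = _random_seq(rng, config.chondrome_size)
    tdna = _random_seq(rng, config.tdna_size)
    bvb = _random_seq(rng, config.bvb_size)
    records = [SeqRecord(c, s, "nuclear chromosome") for c, s in genome.items()]
    records.append(SeqRecord("plastome", plastome, "chloroplast genome"))
    records.append(SeqRecord("chondrome", chondrome, "mitochondrial genome"))
    records.append(SeqRecord(TDNA_ID, tdna, "T-DNA (LB..RB, vector coordinates)"))
    records.append(SeqRecord(BVB_ID, bvb, "binary vector backbone"))
    category = {c: "NUCLEAR" for c in genome}
    category.update(
        {"plastome": "PLASTOME", "chondrome": "CHONDROME", TDNA_ID: "TDNA", BVB_ID: "BVB"}
    )
    return genome, ReferenceCatalog(records, category)


# ---------------------------------------------------------------------------
# event planting

def _unit_seq(catalog: ReferenceCatalog, unit: ArrayUnit) -> str:
    seq = catalog.seq(unit.subject)[unit.s_start : unit.s_end]
    return revcomp(seq) if unit.orient == "-" else seq


def _plant_microhomology(
    genome: dict[str, list], left_seq_end: str, chrom: str, pos: int, mh: int
) -> None:
    """Overwrite the wild type so the right breakpoint begins with the last
    ``mh`` bases of the sequence ending at the left breakpoint."""
    if mh <= 0:
        return
    tail = left_seq_end[-mh:]
    genome[chrom][pos : pos + mh] = list(tail)


def plant_events(
    genome: dict[str, str],
    catalog: ReferenceCatalog,
    events: Sequence[EventSpec],
    config: Optional[SimulationConfig] = None,
) -> tuple[dict[str, str], TruthSet]:
    """Apply integration events; returns the mutant genome and exact truth.

    Microhomology is planted by editing the wild-type sequence just after
    the right breakpoint to repeat the bases just before the left
    breakpoint, so both the mutant junction and the wild-type flanks carry
    the overlap.  At most one event may touch a chromosome.
    """
    config = config or SimulationConfig()
    used: set[str] = set()
    for ev in events:
        for c in (ev.chrom, ev.chrom2):
            if c:
                if c in used:
                    raise SimulationError(f"overlapping events on {c}")
                used.add(c)

    editable = {c: list(s) for c, s in genome.items()}
    truth = TruthSet()

    # ---- first pass: plant microhomologies into the wild type ----
    def _coerce(u) -> ArrayUnit:
        return u if isinstance(u, ArrayUnit) else ArrayUnit(**u)

    for ev in events:
        if ev.kind in ("TDNA_ARRAY", "CPDNA_FILLER_JUNCTION"):
            if ev.microhomology:
                if ev.kind == "TDNA_ARRAY" and ev.units:
                    # genome | first unit junction: rewrite the genomic tail
                    # to repeat the unit head
                    head = _unit_seq(catalog, _coerce(ev.units[0]))[: ev.microhomology]
                    editable[ev.chrom][ev.position - ev.microhomology : ev.position] = list(head)
                else:
                    left_end = "".join(
                        editable[ev.chrom][ev.position - ev.microhomology : ev.position]
                    )
                    _plant_microhomology(
                        editable, left_end, ev.chrom, ev.position + ev.target_deletion, ev.microhomology
                    )
        elif ev.kind in ("TRANSLOCATION_PAIR", "TDNA_FREE_FUSION"):
            mh = ev.microhomology2 if ev.kind == "TRANSLOCATION_PAIR" else ev.microhomology
            if mh:
                # bare fusion: chrom2 prefix + chromA suffix
                left_end = "".join(editable[ev.chrom2][ev.position2 - mh : ev.position2])
                _plant_microhomology(editable, left_end, ev.chrom, ev.position, mh)

    wt = {c: "".join(s) for c, s in editable.items()}
    # microhomology planting edits the wild type itself: propagate the edits
    # to the caller's genome so reference and truth stay consistent
    genome.update(wt)

    # ---- second pass: build mutant chromosomes with provenance ----
    mutant: dict[str, str] = dict(wt)

    def build(chrom_id: str, pieces: list[tuple[str, str, int, int, str, str]]) -> None:
        """pieces: (kind, source_id, s_start, s_end, orient, seq)."""
        prov: list[SourceSegment] = []
        parts: list[str] = []
        cursor = 0
        for kind, sid, s0, s1, orient, seq in pieces:
            if not seq:
                continue
            parts.append(seq)
            prov.append(SourceSegment(cursor, cursor + len(seq), kind, sid, s0, s1, orient))
            cursor += len(seq)
        mutant[chrom_id] = "".join(parts)
        truth.provenance[chrom_id] = prov

    def genomic_piece(chrom: str, a: int, b: int, orient: str = "+"):
        seq = wt[chrom][a:b]
        if orient == "-":
            seq = revcomp(seq)
        return ("GENOMIC", chrom, a, b, orient, seq)

    def unit_pieces(units) -> list:
        out = []
        for u in units:
            if not isinstance(u, ArrayUnit):
                u = ArrayUnit(**u)
            u.kind = catalog.kind_of(u.subject)
            out.append((u.kind, u.subject, u.s_start, u.s_end, u.orient, _unit_seq(catalog, u)))
        return out

    def record_ir_arms(chrom_id: str) -> None:
        prov = truth.provenance[chrom_id]
        arms = []
        non_gen = [p for p in prov if p.kind in ("TDNA", "BVB")]
        for a, b in zip(non_gen, non_gen[1:]):
            if a.orient != b.orient and a.source_id == b.source_id:
                ov = min(a.s_end, b.s_end) - max(a.s_start, b.s_start)
                if ov > 500:  # substantial shared sequence -> foldback-capable
                    arms.append((a.start, a.end, b.start, b.end))
        # a large inverted genomic duplication is itself an inverted repeat
        gen = [p for p in prov if p.kind == "GENOMIC"]
        for a in gen:
            for b in gen:
                if (
                    b.start > a.start
                    and a.orient != b.orient
                    and a.source_id == b.source_id
                    and min(a.s_end, b.s_end) - max(a.s_start, b.s_start) > 500
                ):
                    arms.append((a.start, a.end, b.start, b.end))
        if arms:
            truth.ir_arms[chrom_id] = arms

    for i, ev in enumerate(events):
        eid = ev.name or f"event_{i}_{ev.kind.lower()}"
        units = [u if isinstance(u, ArrayUnit) else ArrayUnit(**u) for u in ev.units]
        for u in units:
            u.kind = catalog.kind_of(u.subject)
        if ev.kind == "TDNA_ARRAY":
            L = len(wt[ev.chrom])
            pieces = (
                [genomic_piece(ev.chrom, 0, ev.position)]
                + unit_pieces(units)
                + [genomic_piece(ev.chrom, ev.position + ev.target_deletion, L)]
            )
            build(ev.chrom, pieces)
            record_ir_arms(ev.chrom)
            anchors = [
                (ev.chrom, ev.position, "LEFT_OF_INSERT"),
                (ev.chrom, ev.position + ev.target_deletion, "RIGHT_OF_INSERT"),
            ]
            junctions = [
                JunctionTruth(
                    left=("GENOMIC", ev.chrom, ev.position, "+"),
                    right=(units[0].kind, units[0].subject, units[0].s_start, units[0].orient),
                    microhomology=ev.microhomology,
                ),
                JunctionTruth(
                    left=(units[-1].kind, units[-1].subject, units[-1].s_end, units[-1].orient),
                    right=("GENOMIC", ev.chrom, ev.position + ev.target_deletion, "+"),
                ),
            ]
            truth.events.append(
                EventTruth(eid, ev.kind, ev, units, junctions, anchors, ev.chrom)
            )
        elif ev.kind in ("TRANSLOCATION_PAIR", "TDNA_FREE_FUSION"):
            A, B = ev.chrom, ev.chrom2
            la, lb = len(wt[A]), len(wt[B])
            der1 = f"fus_{A}_{B}"
            der2 = f"fus_{B}_{A}"
            pieces1 = (
                [genomic_piece(A, 0, ev.position)]
                + unit_pieces(units)
                + [genomic_piece(B, ev.position2, lb)]
            )
            pieces2 = [genomic_piece(B, 0, ev.position2), genomic_piece(A, ev.position, la)]
            del mutant[A]
            del mutant[B]
            build(der1, pieces1)
            build(der2, pieces2)
            record_ir_arms(der1)
            anchors = [
                (A, ev.position, "LEFT_OF_INSERT"),
                (B, ev.position2, "RIGHT_OF_INSERT"),
            ]
            junctions = []
            if units:
                junctions.append(
                    JunctionTruth(
                        left=("GENOMIC", A, ev.position, "+"),
                        right=(units[0].kind, units[0].subject, units[0].s_start, units[0].orient),
                        microhomology=ev.microhomology,
                    )
                )
                junctions.append(
                    JunctionTruth(
                        left=(units[-1].kind, units[-1].subject, units[-1].s_end, units[-1].orient),
                        right=("GENOMIC", B, ev.position2, "+"),
                    )
                )
            else:
                junctions.append(
                    JunctionTruth(
                        left=("GENOMIC", A, ev.position, "+"),
                        right=("GENOMIC", B, ev.position2, "+"),
                        microhomology=ev.microhomology,
                    )
                )
            # the compensating (always T-DNA free) fusion
            junctions.append(
                JunctionTruth(
                    left=("GENOMIC", B, ev.position2, "+"),
                    right=("GENOMIC", A, ev.position, "+"),
                    microhomology=ev.microhomology2,
                )
            )
            truth.events.append(
                EventTruth(eid, ev.kind, ev, units, junctions, anchors, der1)
            )
        elif ev.kind == "INVERTED_DUPLICATION":
            L = len(wt[ev.chrom])
            pieces = (
                [genomic_piece(ev.chrom, 0, ev.dup_end)]
                + unit_pieces(units)
                + [
                    genomic_piece(ev.chrom, ev.dup_start, ev.dup_end, "-"),
                    genomic_piece(ev.chrom, ev.dup_end, L),
                ]
            )
            build(ev.chrom, pieces)
            record_ir_arms(ev.chrom)
            anchors = [
                (ev.chrom, ev.dup_end, "LEFT_OF_INSERT"),
                (ev.chrom, ev.dup_end, "RIGHT_OF_INSERT"),
            ]
            junctions = []
            if units:
                junctions.append(
                    JunctionTruth(
                        left=("GENOMIC", ev.chrom, ev.dup_end, "+"),
                        right=(units[0].kind, units[0].subject, units[0].s_start, units[0].orient),
                    )
                )
            junctions.append(
                JunctionTruth(
                    left=("GENOMIC", ev.chrom, ev.dup_start, "-"),
                    right=("GENOMIC", ev.chrom, ev.dup_end, "+"),
                )
            )
            truth.events.append(
                EventTruth(eid, ev.kind, ev, units, junctions, anchors, ev.chrom)
            )
        elif ev.kind == "CPDNA_FILLER_JUNCTION":
            L = len(wt[ev.chrom])
            fseq = catalog.seq(ev.filler_origin)[ev.filler_src : ev.filler_src + ev.filler_len]
            fkind = catalog.kind_of(ev.filler_origin)
            pieces = [
                genomic_piece(ev.chrom, 0, ev.position),
                (fkind, ev.filler_origin, ev.filler_src, ev.filler_src + ev.filler_len, "+", fseq),
                genomic_piece(ev.chrom, ev.position + ev.target_deletion, L),
            ]
            build(ev.chrom, pieces)
            anchors = [
                (ev.chrom, ev.position, "LEFT_OF_INSERT"),
                (ev.chrom, ev.position + ev.target_deletion, "RIGHT_OF_INSERT"),
            ]
            junctions = [
                JunctionTruth(
                    left=("GENOMIC", ev.chrom, ev.position, "+"),
                    right=("GENOMIC", ev.chrom, ev.position + ev.target_deletion, "+"),
                    filler_seq=fseq,
                    filler_origin=ev.filler_origin,
                    filler_src=ev.filler_src,
                    microhomology=ev.microhomology,
                )
            ]
            chain = [ArrayUnit(ev.filler_origin, ev.filler_src, ev.filler_src + ev.filler_len, "+", fkind)]
            truth.events.append(
                EventTruth(eid, ev.kind, ev, chain, junctions, anchors, ev.chrom)
            )
        else:
            raise SimulationError(f"unknown event kind {ev.kind!r}")

    # untouched chromosomes get identity provenance
    for c in mutant:
        if c not in truth.provenance:
            truth.provenance[c] = [
                SourceSegment(0, len(mutant[c]), "GENOMIC", c, 0, len(mutant[c]), "+")
            ]
    return mutant, truth


# ---------------------------------------------------------------------------
# read simulation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(
    rng: np.random.Generator,
    codes: np.ndarray,
    sub_rate: np.ndarray,
    ins_rate: float,
    del_rate: float,
    phred_mu: np.ndarray,
    phred_sd: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Inject i.i.d. errors; returns (base codes, phred ints) of the read."""
    n = len(codes)
    u = rng.random(n)
    keep = u >= del_rate
    sub = (u < del_rate + sub_rate) & keep  # disjoint slices of u
    subs_new = (codes + rng.integers(1, 4, n)) % 4
    out = np.where(sub, subs_new, codes)
    ins = (rng.random(n) < ins_rate) & keep
    phred = np.clip(np.rint(rng.normal(phred_mu, phred_sd)), 1, 41).astype(np.int64)
    # each kept position emits its base, plus one random inserted base after
    # it when flagged; np.repeat keeps template order
    reps = keep.astype(np.int64) + ins.astype(np.int64)
    b_out = np.repeat(out, reps)
    q_out = np.repeat(phred, reps)
    ins_pos = np.flatnonzero(ins)
    if len(ins_pos):
        second = np.cumsum(reps)[ins_pos] - 1
        b_out[second] = rng.integers(0, 4, len(ins_pos))
    return b_out, q_out


def _second_arm(
    arms: Sequence[tuple[int, int, int, int]],
    start: int,
    end: int,
    strand: str,
) -> Optional[tuple[int, int]]:
    """Template interval of the later-encountered inverted-repeat arm.

    Requires the read to overlap both arms (the foldback exists only when
    the molecule contains the repeat and its reverse complement).
    """
    for a1s, a1e, a2s, a2e in arms:
        ov1 = min(end, a1e) - max(start, a1s)
        ov2 = min(end, a2e) - max(start, a2s)
        if ov1 > 0 and ov2 > 0:
            if strand == "+":
                return (max(start, a2s), min(end, a2e))
            return (max(start, a1s), min(end, a1e))
    return None


def simulate_reads(
    genomes: dict[str, dict[str, str]],
    config: Optional[SimulationConfig] = None,
    truth: Optional[TruthSet] = None,
    rng_seed: Optional[int] = None,
    read_prefix: str = "read",
) -> list[SeqRecord]:
    """Simulate a segregating read pool over mutant/wild-type haplotypes.

    ``genomes`` maps haplotype name ("mutant", "wildtype") to its
    chromosome dict.  Reads are deterministic under the seed; per-read
    truth (template interval, haplotype, provenance slices, degraded arm)
    is recorded into ``truth`` when given.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    mutant = genomes.get("mutant") or {}
    wildtype = genomes.get("wildtype") or {}
    if not mutant and not wildtype:
        raise SimulationError("no haplotypes given")
    base = mutant or wildtype
    total = float(sum(len(s) for s in base.values()))
    mean_len = min(
        float(np.exp(np.log(config.read_median) + config.read_sigma**2 / 2)),
        float(config.read_max),
    )
    n_reads = max(1, int(round(config.depth * total / mean_len)))
    mu_log = np.log(config.read_median)
    hap_chroms: dict[str, tuple[list[str], np.ndarray]] = {}
    for hap_name, g in (("mutant", mutant), ("wildtype", wildtype)):
        if g:
            cs = sorted(g)
            ls = np.array([len(g[c]) for c in cs], dtype=float)
            hap_chroms[hap_name] = (cs, ls / ls.sum())

    codes_cache: dict[tuple[str, str], np.ndarray] = {}

    def codes_of(hap: str, chrom: str) -> np.ndarray:
        key = (hap, chrom)
        if key not in codes_cache:
            from .alignment import encode

            seq = (mutant if hap == "mutant" else wildtype)[chrom]
            codes_cache[key] = encode(seq)
        return codes_cache[key]

    reads: list[SeqRecord] = []
    for i in range(n_reads):
        hap = "mutant" if mutant else "wildtype"
        if mutant and wildtype and rng.random() < config.wt_allele_fraction:
            hap = "wildtype"
        hap_genome = mutant if hap == "mutant" else wildtype
        cs, probs = hap_chroms[hap]
        chrom = cs[int(rng.choice(len(cs), p=probs))]
        clen = len(hap_genome[chrom])
        rlen = int(np.clip(np.exp(rng.normal(mu_log, config.read_sigma)), config.read_min, config.read_max))
        start = int(rng.integers(0, max(1, clen - config.read_min)))
        end = min(clen, start + rlen)
        strand = "+" if rng.random() < 0.5 else "-"
        template = codes_of(hap, chrom)[start:end]
        n = len(template)

        sub_rate = np.full(n, config.mismatch_rate)
        phred_mu = np.full(n, config.phred_mean)
        phred_sd = np.full(n, config.phred_sd)
        low_arm = None
        if (
            config.inverted_arm_quality_drop
            and truth is not None
            and hap == "mutant"
            and chrom in truth.ir_arms
        ):
            low_arm = _second_arm(truth.ir_arms[chrom], start, end, strand)
            if low_arm is not None:
                lo, hi = low_arm[0] - start, low_arm[1] - start
                sub_rate[lo:hi] = min(0.95, config.mismatch_rate * config.low_arm_sub_factor)
                phred_mu[lo:hi] = config.low_phred_mean
                phred_sd[lo:hi] = config.low_phred_sd

        if strand == "-":
            rev = template[::-1]
            template = np.where(rev == 4, 4, 3 - rev)
            sub_rate = sub_rate[::-1].copy()
            phred_mu = phred_mu[::-1].copy()
            phred_sd = phred_sd[::-1].copy()

        b, q = _apply_errors(
            rng,
            template.astype(np.int64),
            sub_rate,
            config.insertion_rate,
            config.deletion_rate,
            phred_mu,
            phred_sd,
        )
        bases = bytes(_BASES[np.clip(b, 0, 3)]).decode("ascii")
        rid = f"{read_prefix}_{i:06d}"
        reads.append(SeqRecord(rid, bases, f"{hap} {chrom}:{start}-{end}{strand}", list(q)))
        if truth is not None:
            if hap == "wildtype":
                # wild-type chromosomes share names with their mutant
                # counterparts; their provenance is always the identity
                prov = [SourceSegment(0, clen, "GENOMIC", chrom, 0, clen, "+")]
            else:
                prov = truth.provenance.get(chrom, [])
            segs = []
            for seg in prov:
                ov0, ov1 = max(start, seg.start), min(end, seg.end)
                if ov1 <= ov0:
                    continue
                if seg.orient == "+":
                    s0 = seg.s_start + (ov0 - seg.start)
                    s1 = seg.s_start + (ov1 - seg.start)
                else:
                    s1 = seg.s_end - (ov0 - seg.start)
                    s0 = seg.s_end - (ov1 - seg.start)
                segs.append(SourceSegment(ov0, ov1, seg.kind, seg.source_id, s0, s1, seg.orient))
            truth.reads[rid] = ReadTruth(rid, hap, chrom, start, end, strand, segs, low_arm)
    return reads


# ---------------------------------------------------------------------------
# named fixture scenarios

def fixture_scenarios() -> dict[str, list[EventSpec]]:
    """The seven named study scenarios, one per structural-variant class.

    Unit coordinates are binary-vector coordinates on the 6 kbp T-DNA
    record (LB repeat at [0,25), RB repeat at the last 25 bases).  Unit
    extents in multi-copy arrays are deliberately distinct so individual
    copies are identifiable from partially overlapping reads.
    """
    T = TDNA_ID
    B = BVB_ID
    return {
        # single full-length T-DNA, transferred DNA starting just inside LB,
        # 13 bp target-site deletion
        "canonical": [
            EventSpec(
                kind="TDNA_ARRAY",
                chrom="chr1",
                position=60_000,
                units=[ArrayUnit(T, 3, 5_980, "+")],
                target_deletion=13,
                microhomology=5,
                name="canonical",
            )
        ],
        # two-copy inverted (head-to-head) array: the second arm of the
        # repeat is emitted at low quality
        "head_to_head": [
            EventSpec(
                kind="TDNA_ARRAY",
                chrom="chr2",
                position=70_000,
                units=[ArrayUnit(T, 3, 5_600, "+"), ArrayUnit(T, 120, 5_450, "-")],
                target_deletion=8,
                name="head_to_head",
            )
        ],
        # eight-copy array in diversified configuration with a BVB fragment
        "eight_unit_array": [
            EventSpec(
                kind="TDNA_ARRAY",
                chrom="chr3",
                position=80_000,
                units=[
                    ArrayUnit(T, 3, 5_950, "+"),
                    ArrayUnit(T, 160, 5_800, "+"),
                    ArrayUnit(T, 320, 5_650, "-"),
                    ArrayUnit(T, 480, 5_500, "+"),
                    ArrayUnit(B, 200, 2_800, "+"),
                    ArrayUnit(T, 640, 5_350, "-"),
                    ArrayUnit(T, 800, 5_200, "-"),
                    ArrayUnit(T, 960, 5_050, "+"),
                    ArrayUnit(T, 1_120, 4_900, "+"),
                ],
                target_deletion=20,
                name="eight_unit_array",
            )
        ],
        # reciprocal chromosome-arm translocation: T-DNA at one fusion,
        # the compensating fusion is T-DNA free
        "reciprocal_translocation": [
            EventSpec(
                kind="TRANSLOCATION_PAIR",
                chrom="chr3",
                position=60_000,
                chrom2="chr5",
                position2=90_000,
                units=[ArrayUnit(T, 3, 5_700, "+"), ArrayUnit(T, 250, 5_900, "-")],
                microhomology=0,
                microhomology2=6,
                name="reciprocal_translocation",
            )
        ],
        # large inverted segmental duplication with a T-DNA at one end and a
        # bare fusion at the other (80 kbp desk-scale analog)
        "inverted_duplication": [
            EventSpec(
                kind="INVERTED_DUPLICATION",
                chrom="chr2",
                dup_start=30_000,
                dup_end=110_000,
                units=[ArrayUnit(T, 3, 5_800, "-")],
                name="inverted_duplication",
            )
        ],
        # 652 bp plastome fragment captured at a genomic junction
        "cpdna_filler": [
            EventSpec(
                kind="CPDNA_FILLER_JUNCTION",
                chrom="chr4",
                position=50_000,
                filler_len=652,
                filler_origin="plastome",
                filler_src=5_000,
                target_deletion=10,
                name="cpdna_filler",
            )
        ],
        # reciprocal fusion with no T-DNA at either junction
        "tdna_free_fusion": [
            EventSpec(
                kind="TDNA_FREE_FUSION",
                chrom="chr1",
                position=100_000,
                chrom2="chr4",
                position2=40_000,
                microhomology=7,
                name="tdna_free_fusion",
            )
        ],
    }


@dataclass
class Scenario:
    name: str
    config: SimulationConfig
    wildtype: dict[str, str]
    mutant: dict[str, str]
    catalog: ReferenceCatalog
    truth: TruthSet
    reads: list[SeqRecord]


def simulate_scenario(
    name: str,
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
) -> Scenario:
    """Generate genome, plant the named scenario's events, simulate reads."""
    events = fixture_scenarios()[name]
    config = config or SimulationConfig(rng_seed=seed)
    genome, catalog = make_genome(config)
    mutant, truth = plant_events(genome, catalog, events, config)
    # plant_events propagates microhomology edits into `genome`, so after
    # planting it IS the wild-type haplotype; the catalog must reflect the
    # same sequences (nuclear records are replaced accordingly)
    for rec in catalog.records:
        if catalog.category[rec.id] == "NUCLEAR":
            rec.bases = genome[rec.id]
    catalog.__post_init__()
    reads = simulate_reads(
        {"mutant": mutant, "wildtype": genome}, config, truth, rng_seed=seed + 1
    )
    return Scenario(name, config, genome, mutant, catalog, truth, reads)
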