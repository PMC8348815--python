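"""Core record types shared by every stage of the pipeline.

Coordinates are uniformly 0-based half-open internally; human-readable
reports convert to 1-based inclusive at the boundary (see
:func:`to_report_coords`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named sequence with optional per-base Phred qualities.

    ``bases`` is upper-case over {A,C,G,T,N}; ``quals`` (when present) holds
    Phred integers in [0, 93] with one entry per base.
    """

    id: str
    bases: str
    description: str = ""
    quals: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"record {self.id!r}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class LocalHit:
    """One scored local alignment between a query interval and a subject.

    ``q_start``/``q_end`` are on the query's stored orientation;
    ``s_start < s_end`` always refers to the forward subject strand, with
    ``strand`` recording the subject orientation of the alignment.
    """

    query_id: str
    q_start: int
    q_end: int
    strand: str
    subject_id: str
    s_start: int
    s_end: int
    identity: float
    score: int
    evalue: float
    aln_len: int
    category: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"bad query interval [{self.q_start},{self.q_end})")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"bad subject interval [{self.s_start},{self.s_end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")


@dataclass
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"{self.chrom}: start {self.start} must be < end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def to_report_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (for human-readable reports)."""
    return start + 1, end


def from_report_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1
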