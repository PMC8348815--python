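"""Readers and writers for the plain-text formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; the wrappers here enforce the
pipeline's validation rules (non-empty sequences, unique ids, ACGTN alphabet
with a logged warning for anything else, Phred/length consistency) and return
:class:`~tdnarray.records.SeqRecord` instances.

All coordinates written to BED/TSV files are 0-based half-open.
"""
from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

from .records import GenomicInterval, LocalHit, SeqRecord

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_NON_ACGTN = re.compile(r"[^ACGTN]")

HITS_COLUMNS = (
    "query",
    "q_start",
    "q_end",
    "strand",
    "subject",
    "s_start",
    "s_end",
    "identity",
    "score",
    "evalue",
    "aln_len",
    "category",
)


class FormatError(ValueError):
    """Malformed input file."""


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_bases(raw: str, record_id: str) -> str:
    bases = raw.upper()
    if _NON_ACGTN.search(bases):
        n_bad = len(_NON_ACGTN.findall(bases))
        log.warning(
            "record %s: %d characters outside {A,C,G,T,N} mapped to N",
            record_id,
            n_bad,
        )
        bases = _NON_ACGTN.sub("N", bases)
    return bases


def read_fasta(path: PathLike) -> list[SeqRecord]:
    """Read a (possibly multi-line, possibly gzipped) FASTA file.

    Lower-case bases are upper-cased; characters outside {A,C,G,T,N} are
    mapped to N with a warning. Empty files and empty sequences raise
    :class:`FormatError` naming the offending record.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                SeqRecord(
                    id=rec.id,
                    bases=_clean_bases(seq, rec.id),
                    description=rec.description[len(rec.id):].strip(),
                )
            )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_fastq(path: PathLike) -> list[SeqRecord]:
    """Read 4-line FASTQ (Phred+33). Length mismatches raise FormatError."""
    records: list[SeqRecord] = []
    with _open_text(path) as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
                seq = str(rec.seq)
                if not seq:
                    raise FormatError(
                        f"{path}: record #{i} ({rec.id!r}) has an empty sequence"
                    )
                records.append(
                    SeqRecord(
                        id=rec.id,
                        bases=_clean_bases(seq, rec.id),
                        description=rec.description[len(rec.id):].strip(),
                        quals=list(rec.letter_annotations["phred_quality"]),
                    )
                )
        except ValueError as exc:  # Biopython signals malformed records this way
            if isinstance(exc, FormatError):
                raise
            raise FormatError(
                f"{path}: malformed FASTQ near record #{len(records)}: {exc}"
            ) from exc
    if not records:
        raise FormatError(f"{path}: no FASTQ records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: PathLike, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.quals is None:
                raise ValueError(f"record {rec.id}: FASTQ output requires qualities")
            qual = "".join(chr(q + 33) for q in rec.quals)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")


def write_bed(intervals: Sequence[GenomicInterval], path: PathLike) -> None:
    """3-column BED, or 6-column when any interval carries a strand."""
    six = any(iv.strand is not None for iv in intervals)
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            if six:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t0\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: fewer than 3 BED columns")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else None
            name = parts[3] if len(parts) >= 4 and parts[3] != "." else ""
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand, name)
            )
    return out


def write_hits_tsv(hits: Sequence[LocalHit], path: PathLike) -> None:
    """One row per LocalHit with the fixed 12-column header."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.q_start}\t{h.q_end}\t{h.strand}\t{h.subject_id}"
                f"\t{h.s_start}\t{h.s_end}\t{h.identity:.6g}\t{h.score}"
                f"\t{h.evalue:.6g}\t{h.aln_len}\t{h.category}\n"
            )


def read_hits_tsv(path: PathLike) -> list[LocalHit]:
    """Read hits written by :func:`write_hits_tsv` (extra columns ignored)."""
    hits: list[LocalHit] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {}
        for col in HITS_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing column {col!r}")
            idx[col] = header.index(col)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                continue
            hits.append(
                LocalHit(
                    query_id=parts[idx["query"]],
                    q_start=int(parts[idx["q_start"]]),
                    q_end=int(parts[idx["q_end"]]),
                    strand=parts[idx["strand"]],
                    subject_id=parts[idx["subject"]],
                    s_start=int(parts[idx["s_start"]]),
                    s_end=int(parts[idx["s_end"]]),
                    identity=float(parts[idx["identity"]]),
                    score=int(parts[idx["score"]]),
                    evalue=float(parts[idx["evalue"]]),
                    aln_len=int(parts[idx["aln_len"]]),
                    category=parts[idx["category"]],
                )
            )
    return hits
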