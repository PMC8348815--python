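"""Selection of T-DNA-containing reads and recruitment of flank reads.

A read is a "T-DNA read" when it has at least one local hit to a T-DNA or
binary-vector-backbone (BVB) catalog record passing the identity (80%),
E-value (1e-50) and length thresholds.  Flank-read recruitment finds the
complementary set: reads matching a genomic flank while carrying no T-DNA,
the evidence base for T-DNA-free fusion points.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional

from .alignment import (
    ScoringScheme,
    SeedIndex,
    build_index,
    count_seed_matches,
    find_local_hits,
)
from .records import GenomicInterval, LocalHit, SeqRecord

CATEGORIES = ("TDNA", "BVB", "NUCLEAR", "PLASTOME", "CHONDROME", "AGROBACTERIUM")

#: catalog category -> chain-unit kind
CATEGORY_KIND = {
    "TDNA": "TDNA",
    "BVB": "BVB",
    "NUCLEAR": "GENOMIC",
    "PLASTOME": "CPDNA",
    "CHONDROME": "CHONDRIO",
    "AGROBACTERIUM": "FILLER",
}


class CatalogError(ValueError):
    pass


@dataclass
class ReferenceCatalog:
    """The annotation catalog: nuclear chromosomes, organelles, T-DNA, BVB."""

    records: list[SeqRecord]
    category: dict[str, str]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CatalogError("duplicate record ids in catalog")
        for rid in ids:
            cat = self.category.get(rid)
            if cat not in CATEGORIES:
                raise CatalogError(f"record {rid!r} has invalid category {cat!r}")
        self._by_id = {r.id: r for r in self.records}

    def seq(self, rid: str) -> str:
        return self._by_id[rid].bases

    def __contains__(self, rid: str) -> bool:
        return rid in self._by_id

    def length(self, rid: str) -> int:
        return len(self._by_id[rid].bases)

    def ids(self, *cats: str) -> list[str]:
        return [r.id for r in self.records if self.category[r.id] in cats]

    def subset(self, *cats: str) -> "ReferenceCatalog":
        recs = [r for r in self.records if self.category[r.id] in cats]
        return ReferenceCatalog(recs, {r.id: self.category[r.id] for r in recs})

    def kind_of(self, rid: str) -> str:
        return CATEGORY_KIND[self.category[rid]]

    def write(self, fasta_path, categories_path) -> None:
        from .io_formats import write_fasta

        write_fasta(self.records, fasta_path)
        with open(categories_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["record", "category"])
            for rec in self.records:
                w.writerow([rec.id, self.category[rec.id]])

    @classmethod
    def from_files(cls, fasta_path, categories_path) -> "ReferenceCatalog":
        from .io_formats import read_fasta

        records = read_fasta(fasta_path)
        category: dict[str, str] = {}
        with open(categories_path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            for row in reader:
                if row:
                    category[row[0]] = row[1]
        return cls(records, category)


@dataclass
class PipelineConfig:
    """Every tunable of the workflow, with the published defaults."""

    tdna_min_identity: float = 0.80
    tdna_max_evalue: float = 1e-50
    tdna_min_aln_len: int = 50
    tile_max_overlap_bp: int = 10
    flank_extract_bp: int = 50_000
    unannotated_min_bp: int = 1_000
    qual_window_nt: int = 200
    qual_step_nt: int = 100
    low_q_threshold: float = 10.0
    aef_bin_bp: int = 100
    aef_group_dist_bp: int = 30_000
    filler_evalue: float = 10.0
    filler_word_size: int = 5
    filler_extension_bp: int = 10
    junction_window_bp: int = 200
    junction_stage1_evalue: float = 1e-5
    expected_insert_chromosome_fraction: float = 0.66
    merge_window: int = 1_000
    lb_slack: int = 3
    border_len: int = 25
    min_depth: int = 10
    coverage_bin_bp: int = 1_000
    kmer: int = 13
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tdna_min_identity",
            "tdna_max_evalue",
            "tile_max_overlap_bp",
            "flank_extract_bp",
            "unannotated_min_bp",
            "qual_window_nt",
            "qual_step_nt",
            "aef_bin_bp",
            "aef_group_dist_bp",
            "filler_evalue",
            "filler_word_size",
            "filler_extension_bp",
            "expected_insert_chromosome_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.tdna_min_identity <= 1.0):
            raise ValueError("tdna_min_identity must be in (0,1]")
        if not (0.0 < self.expected_insert_chromosome_fraction <= 1.0):
            raise ValueError("expected_insert_chromosome_fraction must be in (0,1]")


def build_tdna_index(catalog: ReferenceCatalog, config: PipelineConfig) -> SeedIndex:
    tdna = catalog.subset("TDNA", "BVB")
    if not tdna.ids("TDNA"):
        raise CatalogError("catalog contains no TDNA record")
    return build_index(tdna.records, config.kmer)


def select_tdna_reads(
    reads: Iterable[SeqRecord],
    catalog: ReferenceCatalog,
    config: Optional[PipelineConfig] = None,
    scoring: Optional[ScoringScheme] = None,
    tdna_index: Optional[SeedIndex] = None,
) -> dict[str, list[LocalHit]]:
    """Reads with >=1 passing hit to a TDNA or BVB record.

    Only T-DNA/BVB hits are computed here; annotation against the full
    catalog happens downstream for the selected reads only.
    """
    config = config or PipelineConfig()
    scoring = scoring or ScoringScheme()
    index = tdna_index or build_tdna_index(catalog, config)
    selected: dict[str, list[LocalHit]] = {}
    for read in reads:
        if len(read.bases) < index.k:
            continue
        if count_seed_matches(read, index) < 2:
            continue
        hits = find_local_hits(
            read,
            index,
            scoring,
            min_identity=config.tdna_min_identity,
            max_evalue=config.tdna_max_evalue,
            min_aln_len=config.tdna_min_aln_len,
        )
        if hits:
            for h in hits:
                h.category = catalog.category[h.subject_id]
            selected[read.id] = hits
    return selected


def extract_flanks(
    catalog: ReferenceCatalog,
    anchor: GenomicInterval,
    config: Optional[PipelineConfig] = None,
) -> tuple[SeqRecord, SeqRecord]:
    """50 kbp of sequence on each side of an insertion anchor.

    Flanks are truncated at contig ends; truncation is recorded in the
    record description.
    """
    config = config or PipelineConfig()
    if anchor.chrom not in catalog:
        raise KeyError(f"unknown chromosome {anchor.chrom!r}")
    if catalog.category[anchor.chrom] != "NUCLEAR":
        raise CatalogError(f"anchor {anchor.chrom!r} is not a NUCLEAR record")
    seq = catalog.seq(anchor.chrom)
    L = config.flank_extract_bp
    up_start = max(0, anchor.start - L)
    up = seq[up_start : anchor.start]
    down_end = min(len(seq), anchor.end + L)
    down = seq[anchor.end : down_end]
    up_desc = f"{anchor.chrom}:{up_start}-{anchor.start}"
    if len(up) < L:
        up_desc += " truncated"
    down_desc = f"{anchor.chrom}:{anchor.end}-{down_end}"
    if len(down) < L:
        down_desc += " truncated"
    if not up:
        up = "N"  # degenerate: anchor at contig start
    if not down:
        down = "N"
    upstream = SeqRecord(f"{anchor.chrom}_up_{anchor.start}", up, up_desc)
    downstream = SeqRecord(f"{anchor.chrom}_down_{anchor.end}", down, down_desc)
    return upstream, downstream


def recruit_flank_reads(
    reads: Iterable[SeqRecord],
    flank: SeqRecord,
    tdna_read_ids: set[str],
    catalog: ReferenceCatalog,
    config: Optional[PipelineConfig] = None,
    scoring: Optional[ScoringScheme] = None,
) -> list[str]:
    """Reads matching the flank that carry no T-DNA/BVB hit."""
    config = config or PipelineConfig()
    scoring = scoring or ScoringScheme()
    if not flank.bases:
        raise ValueError("flank sequence is empty")
    flank_index = build_index({flank.id: flank.bases}, config.kmer)
    recruited: list[str] = []
    for read in reads:
        if read.id in tdna_read_ids:
            continue
        if len(read.bases) < flank_index.k:
            continue
        if count_seed_matches(read, flank_index) < 2:
            continue
        hits = find_local_hits(
            read,
            flank_index,
            scoring,
            min_identity=config.tdna_min_identity,
            max_evalue=config.tdna_max_evalue,
            min_aln_len=config.tdna_min_aln_len,
        )
        if hits:
            recruited.append(read.id)
    return recruited
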