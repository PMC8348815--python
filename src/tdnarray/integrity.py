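"""Reference-integrity screening from read alignments.

Candidate misassemblies announce themselves as pileups of alignment
ends: reads cannot span a misjoin, so both flanks accumulate clipped
alignment termini.  Ends are tallied in 100 bp genomic bins; bins with
outstandingly high counts are grouped into candidate regions when less
than 30 kbp apart.  The same alignments feed binned depth-of-coverage
profiles and a simple run-length CNV caller (duplications in a
segregating pool show ~1.5x depth; homozygous deletions drop to ~0).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detection import PipelineConfig
from .records import GenomicInterval


@dataclass
class BinCounts:
    chrom: str
    bin_bp: int
    counts: np.ndarray  # alignment ends per bin

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative bin count")


@dataclass
class CandidateRegion:
    chrom: str
    start: int  # bin-aligned, 0-based half-open
    end: int
    total_ends: int
    n_bins: int
    max_bin_count: int


@dataclass
class CoverageProfile:
    chrom: str
    bin_bp: int
    depth: np.ndarray  # mean depth per bin

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


@dataclass
class CNVCall:
    interval: GenomicInterval
    fold_change: float
    direction: str  # GAIN | LOSS


def count_alignment_ends(
    alignments: Sequence[GenomicInterval],
    chrom_len: int,
    config: Optional[PipelineConfig] = None,
) -> BinCounts:
    """Tally both termini of every alignment into 100 bp bins.

    Each alignment contributes its start position and its last covered
    position (end - 1); bin(p) = floor(p / bin_bp).
    """
    config = config or PipelineConfig()
    bin_bp = config.aef_bin_bp
    n_bins = max(1, -(-chrom_len // bin_bp))
    counts = np.zeros(n_bins, dtype=np.int64)
    chroms = {iv.chrom for iv in alignments}
    if len(chroms) > 1:
        raise ValueError(f"alignments span multiple chromosomes: {sorted(chroms)}")
    for iv in alignments:
        if iv.end > chrom_len or iv.start < 0:
            raise ValueError(
                f"alignment [{iv.start},{iv.end}) exceeds chromosome length {chrom_len}"
            )
        counts[iv.start // bin_bp] += 1
        counts[(iv.end - 1) // bin_bp] += 1
    chrom = next(iter(chroms)) if chroms else ""
    return BinCounts(chrom, bin_bp, counts)


def call_candidate_regions(
    bins: BinCounts,
    end_threshold: Optional[float] = None,
    config: Optional[PipelineConfig] = None,
) -> list[CandidateRegion]:
    """Group high-end bins into candidate misassembly regions.

    ``end_threshold`` defaults to the 99.9th percentile of non-zero bin
    counts (scale-free across depths); bins at/above it seed regions, and
    seeds less than ``aef_group_dist_bp`` (30 kbp) apart merge by single
    linkage.
    """
    config = config or PipelineConfig()
    counts = bins.counts
    if end_threshold is None:
        nz = counts[counts > 0]
        if len(nz) == 0:
            return []
        end_threshold = max(float(np.percentile(nz, 99.9)), 2.0)
    if end_threshold < 1:
        raise ValueError("end_threshold must be >= 1")
    seeds = np.flatnonzero(counts >= end_threshold)
    if len(seeds) == 0:
        return []
    bb = bins.bin_bp
    groups: list[list[int]] = [[int(seeds[0])]]
    for b in seeds[1:]:
        prev_end = (groups[-1][-1] + 1) * bb
        if b * bb - prev_end < config.aef_group_dist_bp:
            groups[-1].append(int(b))
        else:
            groups.append([int(b)])
    out = []
    for g in groups:
        member = counts[g]
        out.append(
            CandidateRegion(
                chrom=bins.chrom,
                start=g[0] * bb,
                end=(g[-1] + 1) * bb,
                total_ends=int(member.sum()),
                n_bins=len(g),
                max_bin_count=int(member.max()),
            )
        )
    out.sort(key=lambda r: (-r.total_ends, r.chrom, r.start))
    return out


def coverage_profile(
    alignments: Sequence[GenomicInterval],
    chrom_len: int,
    bin_bp: int = 1_000,
    chrom: str = "",
) -> CoverageProfile:
    """Mean aligned depth per bin (total aligned bases / bin width)."""
    n_bins = max(1, -(-chrom_len // bin_bp))
    # accumulate via a base-level difference array, then bin
    diff = np.zeros(chrom_len + 1, dtype=np.int64)
    for iv in alignments:
        diff[max(0, iv.start)] += 1
        diff[min(chrom_len, iv.end)] -= 1
        if not chrom:
            chrom = iv.chrom
    depth_per_base = np.cumsum(diff[:-1])
    pad = n_bins * bin_bp - chrom_len
    if pad:
        depth_per_base = np.concatenate([depth_per_base, np.zeros(pad, dtype=np.int64)])
    depth = depth_per_base.reshape(n_bins, bin_bp).sum(axis=1) / bin_bp
    return CoverageProfile(chrom, bin_bp, depth)


def detect_cnv(
    profile: CoverageProfile,
    min_len_bp: int = 50_000,
    gain_fc: float = 1.4,
    loss_fc: float = 0.6,
    genome_median: Optional[float] = None,
) -> list[CNVCall]:
    """Run-length CNV calling against the genome median depth.

    Maximal runs of bins whose fold-change exceeds ``gain_fc`` (or falls
    below ``loss_fc``) and span at least ``min_len_bp`` are reported with
    their mean fold-change.
    """
    depth = profile.depth
    if len(depth) < min_len_bp // profile.bin_bp:
        raise ValueError("profile shorter than min_len_bp")
    med = genome_median if genome_median is not None else float(np.median(depth))
    if med <= 0:
        return []
    fc = depth / med
    min_bins = max(1, min_len_bp // profile.bin_bp)
    calls: list[CNVCall] = []
    for direction, mask in (("GAIN", fc > gain_fc), ("LOSS", fc < loss_fc)):
        start = None
        for i, flag in enumerate(np.concatenate([mask, [False]])):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if i - start >= min_bins:
                    lo = start * profile.bin_bp
                    hi = i * profile.bin_bp
                    calls.append(
                        CNVCall(
                            GenomicInterval(profile.chrom, lo, hi),
                            float(fc[start:i].mean()),
                            direction,
                        )
                    )
                start = None
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls
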