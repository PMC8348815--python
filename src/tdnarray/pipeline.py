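"""End-to-end orchestration: detect -> annotate -> cluster -> resolve ->
junctions -> integrity -> zygosity, with per-stage record counts and a
reproducibility manifest.

T-DNA-free compensating fusions cannot announce themselves through a
T-DNA read, so after resolving T-DNA loci the pipeline probes the
partner flanks of every translocation (and, optionally, user- or
AEF-supplied anchor regions) by recruiting reads that match the flank
but carry no T-DNA, and resolves fusion structures from those reads.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .alignment import ScoringScheme, SeedIndex, build_index, chain_map
from .annotation import ReadAnnotation, annotate_read
from .detection import (
    PipelineConfig,
    ReferenceCatalog,
    select_tdna_reads,
)
from .integrity import (
    BinCounts,
    CandidateRegion,
    CNVCall,
    CoverageProfile,
    call_candidate_regions,
    count_alignment_ends,
    coverage_profile,
    detect_cnv,
)
from .junctions import JunctionReport, analyze_structure_junctions
from .loci import (
    EventCall,
    InsertionStructure,
    LocusGroup,
    ZygosityEstimate,
    build_structure,
    classify_event,
    cluster_loci,
    estimate_zygosity,
)
from .records import GenomicInterval, SeqRecord


@dataclass
class RunManifest:
    version: str
    rng_seed: int
    config: dict
    inputs: dict
    started: float = 0.0
    finished: float = 0.0
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


@dataclass
class PipelineResult:
    structures: list
    fusion_structures: list
    events: list
    junctions: dict  # locus_id -> [JunctionReport]
    zygosity: list
    aef_regions: list
    coverage: dict  # chrom -> CoverageProfile
    cnv_calls: list
    tdna_read_ids: set
    annotations: dict  # read_id -> ReadAnnotation
    manifest: RunManifest

    def summary(self) -> dict:
        by_type: dict[str, int] = {}
        for ev in self.events:
            by_type[ev.event_type] = by_type.get(ev.event_type, 0) + 1
        lb = rb = 0
        bvb_loci = 0
        rb_rb = 0
        for st in self.structures:
            if any(u.kind == "BVB" for u in st.chain):
                bvb_loci += 1
            rb_rb += sum(1 for j in st.internal_junctions if j == "RB_RB")
            for u in st.chain:
                if u.kind != "TDNA":
                    continue
                for b in (u.border_left, u.border_right):
                    if b.startswith("LB"):
                        lb += 1
                    elif b.startswith("RB"):
                        rb += 1
        return {
            "total_loci": len(self.structures),
            "tdna_free_fusions": len(self.fusion_structures),
            "loci_by_event_type": dict(sorted(by_type.items())),
            "loci_with_bvb": bvb_loci,
            "lb_junction_edges": lb,
            "rb_junction_edges": rb,
            "internal_rb_rb_fusions": rb_rb,
        }


def _probe_fusion_anchor(
    reads_by_id: dict,
    catalog: ReferenceCatalog,
    anchor: GenomicInterval,
    tdna_ids: set,
    full_index: SeedIndex,
    read_maps: dict,
    config: PipelineConfig,
    scoring: ScoringScheme,
    annotations_out: dict,
) -> list[InsertionStructure]:
    """Resolve T-DNA-free fusions from split reads at an anchor.

    Reads whose nuclear mapping terminates within the probe window around
    the anchor (and that carry no T-DNA) are the recruitment set: a read
    clipped at the anchor either ends there by chance or continues on the
    fusion partner.  Their annotations are clustered and resolved exactly
    like T-DNA loci.
    """
    window = 2_000
    lo, hi = anchor.start - window, anchor.end + window
    candidates = []
    for rid, maps in read_maps.items():
        if rid in tdna_ids:
            continue
        for m in maps:
            if m.subject_id != anchor.chrom:
                continue
            if lo <= m.s_end <= hi or lo <= m.s_start <= hi:
                candidates.append(rid)
                break
    anns = []
    for rid in candidates:
        if rid in annotations_out:
            anns.append(annotations_out[rid])
        else:
            ann = annotate_read(reads_by_id[rid], full_index, catalog, config, scoring)
            annotations_out[rid] = ann
            anns.append(ann)
    groups, _ = cluster_loci(anns, config)
    structures = []
    for g in groups:
        # a probe site may collect both fusions of a reciprocal pair;
        # chains incompatible with the first consensus form the second
        sub = list(g.annotations)
        ann_by_id = {a.read_id: a for a in sub}
        for _ in range(3):
            if len(sub) < 2:
                break
            st = build_structure(LocusGroup(sub, g.anchors), catalog, config)
            gen_units = [u for u in st.chain if u.kind == "GENOMIC"]
            if len(gen_units) >= 2 and st.left_flank and st.right_flank:
                structures.append(st)
            leftover_ids = {
                ch[0].read_id for ch in st.candidate_chains if ch
            } - set()
            nxt = [ann_by_id[rid] for rid in sorted(leftover_ids) if rid in ann_by_id]
            if len(nxt) >= len(sub) or not nxt:
                break
            sub = nxt
    return structures


def count_spanning_reads(
    reads: Sequence[SeqRecord],
    nuclear_index: SeedIndex,
    interval: GenomicInterval,
    tdna_ids: set,
    margin: int = 500,
) -> tuple[int, int]:
    """(wild-type spanning, insert-supporting) read counts at a locus.

    A read supports the wild-type allele when one contiguous mapping
    covers the whole locus interval plus ``margin`` on both sides; a
    T-DNA read overlapping the interval supports the insertion allele.
    """
    read_maps = {r.id: chain_map(r, nuclear_index) for r in reads}
    return count_spanning_reads_from_maps(read_maps, interval, tdna_ids, margin)


def count_spanning_reads_from_maps(
    read_maps: dict,
    interval: GenomicInterval,
    tdna_ids: set,
    margin: int = 500,
    read_lens: Optional[dict] = None,
) -> tuple[int, int]:
    """Junction-symmetric spanning counts.

    A wild-type read must cover the locus interval plus ``margin`` on both
    sides in one contiguous mapping.  An insertion read must reach a
    junction with a full ``margin`` of genomic flank and continue an equal
    stretch into the insert, so both allele classes are sampled from
    template windows of the same length and the wild-type read fraction
    is an unbiased estimate of the wild-type allele fraction.
    """
    lo = interval.start - margin
    hi = interval.end + margin
    need = margin + (interval.end - interval.start)
    slack = 50  # chain ends jitter around the exact changeover
    wt = 0
    left_j = right_j = 0
    for rid, maps in read_maps.items():
        cmaps = [m for m in maps if m.subject_id == interval.chrom]
        if rid in tdna_ids:
            rlen = (read_lens or {}).get(rid)
            for m in cmaps:
                if m.s_start <= lo and m.s_end >= interval.start - slack:
                    rem = None if rlen is None else (
                        (rlen - m.q_end) if m.strand == "+" else m.q_start
                    )
                    if rem is None or rem >= need:
                        left_j += 1
                        break
                if m.s_end >= hi and m.s_start <= interval.end + slack:
                    rem = None if rlen is None else (
                        m.q_start if m.strand == "+" else (rlen - m.q_end)
                    )
                    if rem is None or rem >= need:
                        right_j += 1
                        break
            continue
        if any(m.s_start <= lo and m.s_end >= hi for m in cmaps):
            wt += 1
    # each junction samples insertion-allele molecules from a template
    # window of the same length as the single wild-type spanning window;
    # averaging the two junction tallies keeps the comparison one-to-one
    insert = (left_j + right_j) / 2
    return wt, insert


def run_pipeline(
    reads: Sequence[SeqRecord],
    catalog: ReferenceCatalog,
    config: Optional[PipelineConfig] = None,
    scoring: Optional[ScoringScheme] = None,
    fusion_probe_anchors: Sequence[GenomicInterval] = (),
    probe_aef_candidates: int = 0,
    run_integrity: bool = True,
) -> PipelineResult:
    """Run every stage on a read pool against a reference catalog.

    ``fusion_probe_anchors`` adds explicit genomic anchors to interrogate
    for T-DNA-free fusions; ``probe_aef_candidates`` additionally probes
    the top-N alignment-end candidate regions.
    """
    config = config or PipelineConfig()
    scoring = scoring or ScoringScheme()
    if not reads:
        raise ValueError("empty read set: nothing to analyze")
    manifest = RunManifest(
        version=__version__,
        rng_seed=config.rng_seed,
        config={k: v for k, v in vars(config).items()},
        inputs={"n_reads": len(reads), "n_catalog_records": len(catalog.records)},
        started=time.time(),
    )

    # stage 1: T-DNA read detection
    selected = select_tdna_reads(reads, catalog, config, scoring)
    tdna_ids = set(selected)
    manifest.stage_counts["tdna_reads"] = len(tdna_ids)

    # stage 2: annotation of selected reads against the full catalog
    full_index = build_index(catalog.records, config.kmer)
    reads_by_id = {r.id: r for r in reads}
    annotations: dict[str, ReadAnnotation] = {}
    for rid in sorted(tdna_ids):
        annotations[rid] = annotate_read(
            reads_by_id[rid], full_index, catalog, config, scoring
        )
    manifest.stage_counts["annotated_reads"] = len(annotations)

    # stage 3: locus clustering and structure resolution
    groups, unanchored = cluster_loci(list(annotations.values()), config)
    structures = [build_structure(g, catalog, config) for g in groups]
    manifest.stage_counts["loci"] = len(structures)
    manifest.stage_counts["unanchored_reads"] = len(unanchored)

    # stage 4: integrity screen (also supplies fusion probe candidates)
    aef_regions: list[CandidateRegion] = []
    coverage: dict[str, CoverageProfile] = {}
    cnv_calls: list[CNVCall] = []
    nuclear_ids = catalog.ids("NUCLEAR")
    nuclear_index = build_index(
        [r for r in catalog.records if r.id in nuclear_ids], config.kmer
    )
    # one chain-level mapping pass serves AEF, coverage, fusion probing
    # and zygosity
    read_maps = {r.id: chain_map(r, nuclear_index) for r in reads}
    if run_integrity:
        per_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in nuclear_ids}
        for rid in sorted(read_maps):
            for m in read_maps[rid]:
                per_chrom[m.subject_id].append(
                    GenomicInterval(m.subject_id, m.s_start, m.s_end, m.strand, m.query_id)
                )
        depths = []
        for chrom in nuclear_ids:
            coverage[chrom] = coverage_profile(
                per_chrom[chrom], catalog.length(chrom), config.coverage_bin_bp, chrom
            )
            depths.append(coverage[chrom].depth)
        genome_median = float(np.median(np.concatenate(depths))) if depths else 0.0
        # an absolute, depth-scaled end threshold: a breakpoint shared by
        # the sample's reads concentrates a sizable fraction of the local
        # depth into one or two bins, while Poisson background stays in
        # single digits
        end_threshold = max(5.0, 0.3 * genome_median)
        for chrom in nuclear_ids:
            bins = count_alignment_ends(per_chrom[chrom], catalog.length(chrom), config)
            bins.chrom = chrom
            aef_regions.extend(call_candidate_regions(bins, end_threshold, config))
            try:
                cnv_calls.extend(
                    detect_cnv(coverage[chrom], genome_median=genome_median)
                )
            except ValueError:
                pass
        aef_regions.sort(key=lambda r: -r.total_ends)
    manifest.stage_counts["aef_candidate_regions"] = len(aef_regions)

    # stage 5: T-DNA-free fusion probing
    probe_anchors = list(fusion_probe_anchors)
    for st in structures:
        if (
            st.left_flank
            and st.right_flank
            and st.left_flank.chrom != st.right_flank.chrom
        ):
            # compensating fusion joins the complementary arms
            probe_anchors.append(
                GenomicInterval(
                    st.left_flank.chrom,
                    st.left_flank.position,
                    st.left_flank.position + 1,
                )
            )
    # contig ends trivially accumulate alignment ends; only interior
    # candidate regions are informative fusion probes
    interior = [
        r
        for r in aef_regions
        if r.start > 2_000 and r.end < catalog.length(r.chrom) - 2_000
    ]
    for region in interior[:probe_aef_candidates]:
        mid = (region.start + region.end) // 2
        probe_anchors.append(GenomicInterval(region.chrom, mid, mid + 1))

    fusion_structures: list[InsertionStructure] = []
    probed: set[tuple[str, int]] = set()
    known = {st.locus_id for st in structures}
    for anchor in probe_anchors:
        key = (anchor.chrom, anchor.start // 10_000)
        if key in probed:
            continue
        probed.add(key)
        for st in _probe_fusion_anchor(
            reads_by_id,
            catalog,
            anchor,
            tdna_ids,
            full_index,
            read_maps,
            config,
            scoring,
            annotations,
        ):
            if st.locus_id in known:
                continue
            known.add(st.locus_id)
            # a probe can surface an insertion with no T-DNA at all
            # (e.g. an organellar capture); those are loci, not bare fusions
            if any(u.kind not in ("GENOMIC", "UNKNOWN_LOWQ") for u in st.chain):
                structures.append(st)
            else:
                fusion_structures.append(st)
    manifest.stage_counts["tdna_free_fusions"] = len(fusion_structures)

    # stage 6: event classification
    events = classify_event(structures, fusion_structures, catalog, cnv_calls)
    manifest.stage_counts["events"] = len(events)

    # stage 7: junction analysis
    junction_reports: dict[str, list[JunctionReport]] = {}
    for st in list(structures) + list(fusion_structures):
        junction_reports[st.locus_id] = analyze_structure_junctions(
            st, catalog, full_index, reads_by_id, annotations, config, scoring
        )
    manifest.stage_counts["junctions"] = sum(len(v) for v in junction_reports.values())

    # stage 8: zygosity from spanning-read counts
    zygosity: list[ZygosityEstimate] = []
    for st in structures:
        lf, rf = st.left_flank, st.right_flank
        if not (lf and rf and lf.chrom == rf.chrom and lf.ref_orient == rf.ref_orient == "+"):
            continue
        lo = min(lf.position, rf.position)
        hi = max(lf.position, rf.position) + 1
        wt, insert = count_spanning_reads_from_maps(
            read_maps,
            GenomicInterval(lf.chrom, lo, hi),
            tdna_ids,
            read_lens={r.id: len(r.bases) for r in reads},
        )
        zygosity.append(estimate_zygosity(st.locus_id, wt, insert))
    manifest.stage_counts["zygosity_calls"] = len(zygosity)

    manifest.finished = time.time()
    return PipelineResult(
        structures=structures,
        fusion_structures=fusion_structures,
        events=events,
        junctions=junction_reports,
        zygosity=zygosity,
        aef_regions=aef_regions,
        coverage=coverage,
        cnv_calls=cnv_calls,
        tdna_read_ids=tdna_ids,
        annotations=annotations,
        manifest=manifest,
    )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
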