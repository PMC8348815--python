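"""Static report bundle: TSV/BED/text tables plus per-locus structure
diagrams (coloured unit bars with vector coordinates and border labels,
flank positions in 1-based reference coordinates)."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from .detection import PipelineConfig
from .pipeline import PipelineResult, sha256_file
from .records import GenomicInterval, to_report_coords

UNIT_COLOURS = {
    "GENOMIC": "#7fbf7f",
    "TDNA": "#b22222",
    "BVB": "#f4a582",
    "CPDNA": "#2ca02c",
    "CHONDRIO": "#6a9fb5",
    "FILLER": "#aaaaaa",
    "UNKNOWN_LOWQ": "#cccccc",
}


def _structures_tsv(result: PipelineResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tleft_chrom\tleft_pos_1based\tright_chrom\tright_pos_1based"
            "\ttarget_site_deletion_bp\tn_reads\tflags\tchain\tinternal_junctions\n"
        )
        for st in list(result.structures) + list(result.fusion_structures):
            lf, rf = st.left_flank, st.right_flank
            chain = ";".join(
                f"{u.kind}:{u.subject_id}:{u.s_start + 1}-{u.s_end}:{u.orientation}"
                f":{u.border_left}/{u.border_right}"
                for u in st.chain
            )
            fh.write(
                f"{st.locus_id}\t{lf.chrom if lf else '.'}\t{lf.position + 1 if lf else '.'}"
                f"\t{rf.chrom if rf else '.'}\t{rf.position + 1 if rf else '.'}"
                f"\t{st.target_site_deletion_bp}\t{len(st.supporting_reads)}"
                f"\t{','.join(st.flags) or '.'}\t{chain}"
                f"\t{','.join(st.internal_junctions) or '.'}\n"
            )


def _junctions_tsv(result: PipelineResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "junction_id\tleft_origin\tright_origin\tfiller_len\tfiller_origin"
            "\tmicrohomology_len\n"
        )
        for reports in result.junctions.values():
            for r in reports:
                left = f"{r.left_origin[0]}:{r.left_origin[1]}:{r.left_origin[2] + 1}"
                right = f"{r.right_origin[0]}:{r.right_origin[1]}:{r.right_origin[2] + 1}"
                fh.write(
                    f"{r.junction_id}\t{left}\t{right}\t{len(r.filler_seq)}"
                    f"\t{r.filler_origin or '.'}\t{r.microhomology_len}\n"
                )


def _zygosity_tsv(result: PipelineResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\twt_allele_read_fraction\tcall\n")
        for z in result.zygosity:
            frac = "nan" if z.wt_allele_read_fraction != z.wt_allele_read_fraction else f"{z.wt_allele_read_fraction:.4f}"
            fh.write(f"{z.locus_id}\t{frac}\t{z.call}\n")


def _aef_bed(result: PipelineResult, path: Path) -> None:
    with open(path, "w") as fh:
        for r in result.aef_regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\taef_region\t{r.total_ends}\t.\n")


def _cnv_bed(result: PipelineResult, path: Path) -> None:
    with open(path, "w") as fh:
        for c in result.cnv_calls:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.direction}\t{c.fold_change:.3f}\t.\n"
            )


def _coverage_tsv(result: PipelineResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbin_start\tbin_end\tdepth\n")
        for chrom in sorted(result.coverage):
            prof = result.coverage[chrom]
            for i, d in enumerate(prof.depth):
                fh.write(
                    f"{chrom}\t{i * prof.bin_bp}\t{(i + 1) * prof.bin_bp}\t{d:.3f}\n"
                )


def _summary_txt(result: PipelineResult, path: Path) -> None:
    s = result.summary()
    with open(path, "w") as fh:
        fh.write("T-DNA insertion analysis summary\n")
        fh.write("================================\n")
        for key, val in s.items():
            fh.write(f"{key}: {json.dumps(val)}\n")


def _diagram(structure, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(max(6, len(structure.chain) * 1.6), 2.2))
    x = 0.0
    for u in structure.chain:
        w = max(len(u) / 1000.0, 0.4)
        ax.add_patch(
            Rectangle((x, 0.35), w, 0.3, color=UNIT_COLOURS.get(u.kind, "#888888"))
        )
        arrow = ">" if u.orientation == "+" else "<"
        label = f"{u.kind}{arrow}"
        if u.kind != "GENOMIC":
            label += f"\n{u.s_start + 1}-{u.s_end}"
        else:
            label += f"\n{u.subject_id}"
        ax.text(x + w / 2, 0.5, label, ha="center", va="center", fontsize=7)
        if u.border_left not in ("NA",):
            ax.text(x, 0.72, u.border_left, ha="left", fontsize=6, rotation=30)
        if u.border_right not in ("NA",):
            ax.text(x + w, 0.2, u.border_right, ha="right", fontsize=6, rotation=30)
        x += w + 0.08
    for fl, xx in ((structure.left_flank, 0.0), (structure.right_flank, x)):
        if fl:
            ax.text(
                xx, 0.05, f"{fl.chrom}:{fl.position + 1}", fontsize=7, ha="left"
            )
    ax.set_xlim(-0.2, x + 0.2)
    ax.set_ylim(0, 1)
    ax.axis("off")
    ax.set_title(structure.locus_id, fontsize=9)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def render_report(
    result: PipelineResult,
    outdir,
    config: Optional[PipelineConfig] = None,
    diagrams: bool = True,
) -> dict:
    """Write the full report bundle; returns {filename: sha256}.

    Regeneration from the same result is byte-identical (the manifest,
    which carries wall-clock timestamps, is checksummed over its stable
    fields only).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    writers = {
        "structures.tsv": _structures_tsv,
        "junctions.tsv": _junctions_tsv,
        "zygosity.tsv": _zygosity_tsv,
        "aef_regions.bed": _aef_bed,
        "cnv.bed": _cnv_bed,
        "coverage.tsv": _coverage_tsv,
        "summary.txt": _summary_txt,
    }
    checksums = {}
    for fname, writer in writers.items():
        path = outdir / fname
        writer(result, path)
        checksums[fname] = sha256_file(path)
    if diagrams:
        ddir = outdir / "diagrams"
        ddir.mkdir(exist_ok=True)
        for st in list(result.structures) + list(result.fusion_structures):
            safe = st.locus_id.replace(":", "_").replace("/", "_")
            _diagram(st, ddir / f"{safe}.png")
    result.manifest.outputs = checksums
    with open(outdir / "manifest.json", "w") as fh:
        fh.write(result.manifest.to_json())
    return checksums
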