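# tdnarray

Resolution of T-DNA insertion loci, array structures and chromosome
fusions in plant genomes from Oxford Nanopore (ONT) long reads.

## The problem

*Agrobacterium*-mediated transformation integrates the T-DNA segment of a
binary vector at essentially random positions in the plant nuclear
genome. What actually lands at an insertion site is frequently not one
clean T-DNA copy but a concatenated array of complete and truncated
copies in tandem and inverted configurations, sometimes with binary
vector backbone (BVB), organellar DNA (cpDNA) or short filler sequence
captured at the junctions — and insertion mutagenesis can drag whole
chromosome arms along with it, producing reciprocal translocations whose
compensating fusion carries no T-DNA at all. Short flanking-sequence tags
see only one junction and routinely misrepresent such loci. Long reads
span entire insertion structures, but turning a pool of noisy 10–30 kbp
reads into a locus-level model takes a dedicated workflow.

`tdnarray` implements that workflow as a tested Python library and CLI:

* **T-DNA read detection** — seed-and-extend local alignment (a BLASTn
  stand-in with Karlin–Altschul E-values) selects reads with a hit to
  T-DNA/BVB at ≥80% identity and E ≤ 1e-50.
* **Greedy tiling annotation** — each read is tiled with catalog hits in
  decreasing score order; a hit overlapping an accepted segment by more
  than 10 bp is discarded. Unannotated stretches >1 kbp are tracked and
  cross-referenced with a 200 nt/100 nt sliding mean-Phred track: the
  second arm of an inverted T-DNA repeat is sequenced at Phred ≈ 7 and
  often cannot be annotated directly.
* **Locus resolution** — reads cluster by the reference projection of
  their genome::insert changeovers; per-read unit chains are oriented,
  merged by unit-level overlap assembly, and reduced to a consensus
  chain. Disagreements on a unit's extent resolve to the largest extent
  any single read supports, and low-quality inverted-repeat arms are
  rescued from opposite-direction reads. LB/RB border status (25 bp
  border repeats; vector position 1 at the left end of LB) and internal
  RB::RB fusions are annotated on every T-DNA unit.
* **Event classification** — canonical insertion, complex array,
  translocation fusion (with reciprocal-partner pairing), T-DNA-free
  fusion, inverted duplication (corroborated by binned coverage), and
  cpDNA insertion.
* **Junction analysis** — filler DNA extraction with a cascaded origin
  search (ordinary alignment; then a short-match search at E ≤ 10; then
  the same after extending the filler by 10 bases of context) and exact
  suffix/prefix microhomology.
* **Reference integrity (alignment-end binning)** — read-alignment ends
  are tallied in 100 bp bins; outstanding bins group into candidate
  misassembly regions when <30 kbp apart. Binned coverage feeds a simple
  run-length CNV caller.
* **Simulator** — synthetic genomes with planted arrays, translocations,
  inverted duplications, fillers and microhomology, plus ONT-like reads
  (log-normal lengths, i.i.d. errors, the inverted-repeat quality drop)
  with exact truth records for every junction, unit and read.

## Worked example

Simulate a segregating T2 pool over the default five-chromosome
synthetic genome carrying one canonical insertion on chr1 (full-length
T-DNA, 13 bp target-site deletion, 5 bp microhomology at the left
junction), then run the pipeline:

```bash
tdnarray simulate --outdir sim --seed 0 --scenario canonical
tdnarray run --reads sim/reads.fastq --catalog sim/catalog.fasta \
             --categories sim/categories.tsv --outdir out
```

`run` prints the per-line summary:

```json
{
  "total_loci": 1,
  "tdna_free_fusions": 0,
  "loci_by_event_type": { "CANONICAL_INSERTION": 1 },
  "loci_with_bvb": 0,
  "lb_junction_edges": 1,
  "rb_junction_edges": 1,
  "internal_rb_rb_fusions": 0
}
```

and `out/structures.tsv` holds the resolved locus (coordinates 1-based
in reports):

```
locus_id                left_pos  right_pos  tsd  n_reads  chain
chr1:60002--chr1:60013  60003     60014      11   27       GENOMIC:chr1:34048-60002:+;TDNA:pTD1:4-5984:+:LB_INTACT/RB_TRUNCATED;GENOMIC:chr1:60013-101179:+
```

The chain reads: left genomic flank, one T-DNA unit whose transferred
DNA starts at vector position 4 (LB intact) and stops short of RB
(RB truncated), then the right genomic flank — the planted truth, with
the 13 bp target-site deletion recovered as 11 bp (junction estimates
jitter by a base or two at ONT error rates). `out/junctions.tsv` reports
the planted 5 bp microhomology at the genome::LB junction, and
`out/zygosity.tsv` calls the locus SEGREGATING with a wild-type read
fraction of 0.52 (a selected T2 pool carries the insertion on 2/3 of
chromosomes; the spanning-read estimate runs conservative at 30× depth).
`out/diagrams/` contains one structure diagram per locus.

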