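# Methods

This note documents the models, algorithms and numerical choices behind
`tdnarray`, what the synthetic data do and do not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Local alignment

Queries are seeded with exact k-mers (default k = 13) stored in a
canonical-form index covering both strands of every catalog record.
Seeds are chained greedily by colinearity (diagonal tolerance 100,
query gap ≤ 1 kbp), and a second chaining level rejoins chains split by
accumulated indel drift: two chains merge only when they effectively
abut on *both* query and subject (gap ≤ 300 bp) and sit within 500
diagonals. The both-axes condition is what preserves genuine structural
changeovers — a junction filler or target-site deletion leaves unmatched
query sequence between the chains and therefore stays split, while pure
drift splits overlap and rejoin. Each chain is extended by a banded
affine-gap Smith–Waterman (match +2, mismatch −3, gap open −5, gap
extend −2; a length-L gap costs open + L·extend) whose band is the
chain's observed diagonal range plus a 150-diagonal pad — far cheaper
than a band proportional to the chain span, and sufficient because the
chain itself witnesses the drift. For small problems (query × subject ≤
4·10⁶ cells) an exact full Smith–Waterman pass supplements the seeded
path, so the best reported hit on such pairs is the true local optimum;
the validation suite checks this against Biopython's independent
`PairwiseAligner` implementation.

Hit significance uses the Karlin–Altschul form E = K·m·n·e^(−λS).
λ is solved numerically (Brent) from the ungapped moment equation at
uniform base frequencies; K defaults to 0.3, a conventional ungapped
DNA value. E-values here only reproduce published filter thresholds
(1e-50 for read selection; 10 for the short-match filler search) — a
factor-of-few error in K moves log₁₀E by well under one unit and has no
effect at those cutoffs.

Identity is matches / alignment columns (gaps included). Defaults for
T-DNA read selection: identity ≥ 0.80, E ≤ 1e-50, and an alignment-length
floor of 50 bp. The published procedure states only the first two; the
floor makes the identity threshold meaningful, since sub-50 bp matches at
80% identity arise freely by chance.

## Tiling annotation and quality tracks

Hits tile onto a read greedily in decreasing-score order; a hit is
discarded iff its read-interval overlap with any accepted segment
*exceeds* 10 bp (an exactly-10 bp overlap is kept). Score ties break by
longer alignment, then smaller read start, then subject id — the
published rule specifies only "decreasing score", and the tie-break makes
tiling independent of input order. Overlap is measured on read
coordinates only. Both members of a permitted ≤10 bp overlap are
reported untrimmed.

Unannotated intervals strictly longer than 1 kbp become gaps. Mean Phred
is computed in 200 nt windows stepped by 100 nt (anchored at read
position 0). Gaps whose windows average ≤ 10 (chosen with margin above
the ≈7 observed in the degraded arm of inverted repeats) are LOW_QUALITY,
and additionally CANDIDATE_INVERTED_ARM when flanked by T-DNA/BVB
segments on both sides.

## Locus resolution

Changeover anchors are the reference projections of boundaries between a
genomic segment (≥200 bp) and a non-genomic neighbour, or between two
genomic segments that do not continue each other on the reference.
Anchors cluster per chromosome by single linkage within 1 kbp (far below
any inter-locus distance of interest, above ONT breakpoint jitter), and
clusters sharing a read merge, so the two flanks of one insertion form
one locus.

Each read's tiled segments become an ordered unit chain (segments under
150 bp are treated as noise; reference-contiguous same-subject segments
rejoin; gaps become UNKNOWN_LOWQ units). Chains are oriented so the
first genomic unit runs forward and are then assembled at unit level:
the longest chain seeds a consensus, and every other chain is placed at
its best unambiguous offset in either orientation, with extents compared
side-wise against the good-quality member median (tolerance 60 bp,
read-edge-clipped sides exempt). Three rules do the scientific work:

* **Largest single-read extent.** Where reads disagree on a unit's
  boundary, the resolved extent takes, per side, the furthest coordinate
  observed by any single read with a reliable (non-clipped, good-quality)
  alignment end — the "largest possible T-DNA" consistent with the reads.
* **Low-quality rescue.** Extent observations from segments at mean
  Phred ≤ 10 (the degraded second arm of an inverted repeat) never vote
  on unit identity and never set extents when a good-quality observation
  exists; an UNKNOWN_LOWQ placeholder is replaced outright by a
  well-annotated unit at the same consensus position, which in practice
  comes from a read of the opposite direction, where that arm was
  sequenced first and cleanly.
* **Duplicate compaction.** Adjacent consensus positions describing the
  same unit (offset drift between partially overlapping reads) collapse,
  *unless* some single read shows both positions as distinct units —
  which protects genuine tandem copies of identical extent.

Chains with no valid placement against the consensus are reported as
candidate chains; when they exceed 20% of the locus reads the structure
is flagged UNRESOLVED (a probe site that collects both fusions of a
reciprocal pair resolves these leftovers into a second structure).
Single-read structures carry LOW_SUPPORT rather than being suppressed.

Flank anchors take the median junction coordinate over reads that
actually reach the changeover. Target-site deletion is the reference gap
between the left and right flank anchors. Border status: a T-DNA unit is
LB_INTACT when its vector start lies within 3 bp of position 1 (LB
nicking leaves position 4, 1-based, as the start of transferred DNA),
RB_INTACT within 3 bp of the vector end; array-internal edges are
INTERNAL, and adjacent +/− units meeting at their high-vector-coordinate
ends are flagged RB::RB.

## Event classification

Flanks on different chromosomes → TRANSLOCATION_FUSION; same chromosome
with an inverted right flank → INVERTED_DUPLICATION (corroborated, when
coverage is available, by a GAIN region within 25 kbp of the anchor);
a chain whose only insert material is organellar → CPDNA_INSERTION
(also emitted additionally when cpDNA appears inside a T-DNA array);
one T-DNA unit → CANONICAL_INSERTION; several units → COMPLEX_ARRAY;
two genomic arms with nothing between → TDNA_FREE_FUSION. Fusion-class
calls naming the same chromosome pair with breakpoints within 50 kbp are
cross-annotated as reciprocal partners.

T-DNA-free fusions cannot announce themselves through a T-DNA read, so
the pipeline probes the partner flanks of every translocation and
(optionally) the top interior alignment-end candidate regions: reads
whose nuclear mapping terminates near the probe anchor and that carry no
T-DNA are annotated and resolved exactly like T-DNA loci. Contig ends
are excluded from probing — read termini pile up there trivially.

## Junction analysis

Each junction is examined on a representative read: 100 bp of assigned
context per side plus everything between the assignments (inserts up to
2 kbp between two genomic units are treated as one composite
genome::genome junction — the organellar-capture case; larger inserts
are structural units, not filler). The filler is the maximal window
interval not covered by alignments consistent with the junction's own
flanking origins. Its origin is sought in three stages: ordinary local
hits (E ≤ 1e-5 on the window; plain BLASTn-default E = 10 on a 200 bp
query floods the junction with noise, so the stage-1 cutoff is stricter
and configurable); a short-match search of the bare filler at E ≤ 10
implemented as exhaustive local DP over the catalog (strictly more
sensitive than a word-size-5 seeded search); and the same search after
extending the filler by 10 bases of context per side, which rescues
fillers copied from sequence adjacent to the break. Origins of sub-20 bp
fillers are intrinsically unreliable (a 9 bp perfect match can pass
E ≤ 10 against a small catalog and fail against a large one) and may be
reported as UNKNOWN.

Microhomology is the longest exact suffix of the left-joined reference
end equal to a prefix of the right-joined end. Junction coordinates
estimated from noisy reads jitter by a few bases, so the computation
scans a ±3 bp offset neighbourhood on both sides and keeps the best
overlap; this recovers planted microhomologies at the cost of a small
upward noise floor (a spurious overlap of 2–3 bp is common by chance).

## Reference integrity

Every alignment contributes its start and its last covered position to
100 bp bins. Candidate regions are maximal single-linkage groups of
bins at/above a threshold with gaps under 30 kbp. The library default
threshold is the 99.9th percentile of non-zero bins (scale-free across
depths); the pipeline instead passes an absolute, depth-scaled threshold
(max(5, 0.3 × genome median coverage)) because at desk-scale chromosome
sizes a top-permille percentile degenerates to the single maximum bin.
Coverage is total aligned bases per 1 kbp bin; CNV calling is deliberate
run-length thresholding against the genome median (gain > 1.4, loss <
0.6, minimum 50 kbp) — change-point methods are out of scope. A
duplication carried on 2/3 of the chromosomes of a selected pool is
expected near fold-change 5/3, within the caller's gain band.

Interval-level evidence (coverage, end bins, spanning counts, fusion
probes) uses chain-level mappings without DP extension; endpoints are
accurate to roughly the seed length, well inside a 100 bp bin.

## Zygosity

With full selection on the resistance marker, 2/3 of the chromosomes of
a T2 pool carry the insertion. The wild-type allele fraction at a locus
is estimated from spanning reads: a wild-type read must cover the locus
interval plus a 500 bp margin in one contiguous mapping; an
insertion-allele read must reach a junction with the same margin of
genomic flank and continue an equal stretch into the insert, and the two
junction tallies are averaged so both allele classes are sampled from
template windows of equal length. Calls: HOMOZYGOUS below 0.15,
SEGREGATING in [0.15, 0.60] (centred on the 1/3 expectation),
UNDETERMINED otherwise or below 10 informative reads. At 30× depth the
estimator runs slightly conservative (wild-type fraction ≈ 0.4 on
simulated 1/3 pools, mostly because junction reads with marginal T-DNA
overlap escape selection) — well inside the SEGREGATING band, and the
HOMOZYGOUS limit (fraction → 0) is unaffected.

## Synthetic data

The generator emulates: five 150 kbp chromosomes (uniform random
sequence), a 20 kbp plastome, a 10 kbp chondrome, a 6 kbp T-DNA record
with 25 bp LB/RB repeats at its ends (vector coordinates, LB at position
1) and a 3 kbp BVB record; planted events with exact truth (breakpoints,
unit chains in vector coordinates, filler sequences and origins,
microhomology constructed by editing the wild type so both alleles carry
the overlap, per-read source intervals); ONT-like reads with log-normal
lengths (median 15 kbp, σ_log 0.6, truncated to [1, 100] kbp), i.i.d.
per-base errors (mismatch 0.04, insertion 0.03, deletion 0.04), nominal
base quality N(13, 3), and a positional inverted-repeat artifact: when a
molecule contains both arms of a planted inverted repeat, the arm
encountered second in the read's own direction is emitted at quality
N(7, 1.5) with a tripled substitution rate, whichever strand the read
runs on. Haplotype choice follows the segregation expectation
(wild-type allele fraction 1/3 by default). Everything is deterministic
under the seed, to the byte in FASTQ output.

Not emulated: homopolymer-dependent errors, chimeric/adapter artifacts,
base-composition bias, repeat families in the genomic background, and
signal-level pore physics. Passing tests therefore demonstrate the
pipeline's logic under calibrated noise, not performance on real repeat-
rich plant genomes; uniform random backgrounds make genomic alignment
easier than reality, which is precisely why the validation focuses on
structural recovery (arrays, fusions, fillers) rather than mappability.

The named scenarios mirror the structural-variant classes reported for
real insertion lines, scaled to desk size: canonical insertion with a
13 bp target-site deletion; two-copy head-to-head array exercising the
quality-drop rescue; an eight-copy array with an internal BVB fragment
(unit extents deliberately distinct so copies are identifiable from
partial overlaps); a reciprocal translocation with T-DNA at one fusion
only; an 80 kbp inverted duplication (desk-scale analog of a reported
0.8 Mbp event); a 652 bp plastome capture; and a reciprocal fusion with
no T-DNA at all. Validation problem sizes — 30× pools over ~786 kbp of
catalog per scenario, 200 oracle pairs, 100 zygosity replicates — were
chosen so the whole suite completes in tens of minutes on one CPU.

## Known limitations

* Arrays of adjacent identical-extent, identical-orientation copies are
  only resolved when some single read spans the repeat pair; otherwise
  compaction merges them (count underestimate). Distinct truncations,
  orientations, or interleaved BVB — the common real cases — resolve.
* The unit-chain assembler assumes one structure per locus cluster;
  allelic heterogeneity beyond wild-type/insertion is not modelled.
* Junction filler at homologous same-subject junctions can be absorbed
  into one gapped alignment when shorter than roughly the gap-open cost
  divided by the match score times flanking gain (in practice <10 bp at
  same-subject junctions); heterologous junctions are unaffected.
* E-values use ungapped Karlin–Altschul parameters with a conventional K;
  they are filters, not statistics.
* The CNV caller reports maximal threshold runs; a single sub-threshold
  bin splits a region, so called spans can undershoot the true extent.
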