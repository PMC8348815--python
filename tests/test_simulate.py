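import io

import edlib
import numpy as np
import pytest

from tdnarray.io_formats import write_fastq
from tdnarray.records import revcomp
from tdnarray.simulate import (
    ArrayUnit,
    BORDER_LEN,
    EventSpec,
    SimulationConfig,
    SimulationError,
    TDNA_ID,
    make_genome,
    plant_events,
    simulate_reads,
    fixture_scenarios,
    simulate_scenario,
)


def small_config(**kw):
    defaults = dict(
        rng_seed=5,
        chrom_sizes={"chr1": 40_000},
        plastome_size=5_000,
        chondrome_size=2_000,
        read_median=6_000,
        read_min=800,
        depth=20.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def fastq_bytes(reads):
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "r.fq"
        write_fastq(reads, p)
        return p.read_bytes()


class TestMakeGenome:
    def test_deterministic_under_seed(self):
        g1, c1 = make_genome(small_config())
        g2, c2 = make_genome(small_config())
        assert g1 == g2
        assert [r.bases for r in c1.records] == [r.bases for r in c2.records]

    def test_different_seeds_differ(self):
        g1, _ = make_genome(small_config())
        g2, _ = make_genome(small_config(rng_seed=6))
        assert g1 != g2

    def test_borders_at_vector_ends(self):
        _, catalog = make_genome(small_config())
        tdna = catalog.seq(TDNA_ID)
        lb = tdna[:BORDER_LEN]
        rb = tdna[-BORDER_LEN:]
        assert len(lb) == len(rb) == 25
        # position 1 (1-based) is the left end of LB
        assert tdna.index(lb) == 0


class TestPlantEvents:
    def test_empty_event_list_is_identity(self):
        cfg = small_config()
        genome, catalog = make_genome(cfg)
        mutant, truth = plant_events(genome, catalog, [], cfg)
        assert mutant == genome
        assert truth.events == []

    def test_canonical_deletion_recorded(self):
        cfg = small_config()
        genome, catalog = make_genome(cfg)
        ev = EventSpec(
            kind="TDNA_ARRAY",
            chrom="chr1",
            position=20_000,
            units=[ArrayUnit(TDNA_ID, 3, 5_900, "+")],
            target_deletion=13,
        )
        mutant, truth = plant_events(genome, catalog, [ev], cfg)
        (et,) = truth.events
        assert et.anchors == [
            ("chr1", 20_000, "LEFT_OF_INSERT"),
            ("chr1", 20_013, "RIGHT_OF_INSERT"),
        ]
        insert = catalog.seq(TDNA_ID)[3:5_900]
        assert mutant["chr1"] == genome["chr1"][:20_000] + insert + genome["chr1"][20_013:]

    def test_head_to_head_records_inverted_arms(self):
        cfg = small_config()
        genome, catalog = make_genome(cfg)
        ev = EventSpec(
            kind="TDNA_ARRAY",
            chrom="chr1",
            position=20_000,
            units=[ArrayUnit(TDNA_ID, 3, 5_600, "+"), ArrayUnit(TDNA_ID, 120, 5_450, "-")],
        )
        _, truth = plant_events(genome, catalog, [ev], cfg)
        assert "chr1" in truth.ir_arms
        ((a1s, a1e, a2s, a2e),) = truth.ir_arms["chr1"]
        assert a1s == 20_000 and a2e - a2s == 5_450 - 120

    def test_translocation_produces_two_derived_chromosomes(self):
        cfg = small_config(chrom_sizes={"chr1": 40_000, "chr2": 40_000})
        genome, catalog = make_genome(cfg)
        ev = EventSpec(
            kind="TDNA_FREE_FUSION",
            chrom="chr1",
            position=25_000,
            chrom2="chr2",
            position2=10_000,
            microhomology=7,
        )
        mutant, truth = plant_events(genome, catalog, [ev], cfg)
        assert set(mutant) == {"fus_chr1_chr2", "fus_chr2_chr1"}
        der1 = mutant["fus_chr1_chr2"]
        assert der1 == genome["chr1"][:25_000] + genome["chr2"][10_000:]
        # planted microhomology: the bases after the chr1 breakpoint equal
        # the bases before it on the fusion partner's side
        assert genome["chr1"][25_000:25_007] == genome["chr2"][9_993:10_000]

    def test_overlapping_events_rejected(self):
        cfg = small_config()
        genome, catalog = make_genome(cfg)
        ev = EventSpec(
            kind="TDNA_ARRAY",
            chrom="chr1",
            position=20_000,
            units=[ArrayUnit(TDNA_ID, 3, 5_900, "+")],
        )
        with pytest.raises(SimulationError):
            plant_events(genome, catalog, [ev, ev], cfg)


class TestSimulateReads:
    def test_byte_identical_fastq_under_seed(self):
        cfg = small_config()
        genome, catalog = make_genome(cfg)
        r1 = simulate_reads({"wildtype": genome}, cfg, rng_seed=42)
        r2 = simulate_reads({"wildtype": genome}, cfg, rng_seed=42)
        assert fastq_bytes(r1) == fastq_bytes(r2)
        r3 = simulate_reads({"wildtype": genome}, cfg, rng_seed=43)
        assert fastq_bytes(r1) != fastq_bytes(r3)

    def test_empirical_error_rates_near_configured(self):
        cfg = small_config(chrom_sizes={"chr1": 100_000}, depth=30.0)
        genome, catalog = make_genome(cfg)
        truth_holder = __import__("tdnarray.simulate", fromlist=["TruthSet"]).TruthSet()
        reads = simulate_reads({"wildtype": genome}, cfg, truth_holder, rng_seed=9)
        assert len(reads) > 300
        subs = dels = ins = aligned = 0
        for read in reads[:400]:
            rt = truth_holder.reads[read.id]
            template = genome[rt.chrom][rt.start : rt.end]
            if rt.strand == "-":
                template = revcomp(template)
            res = edlib.align(read.bases, template, task="path", mode="NW")
            for n, op in _cigar_ops(res["cigar"]):
                if op == "X":
                    subs += n
                elif op == "D":
                    dels += n  # deletion in read relative to template
                elif op == "I":
                    ins += n
            aligned += len(template)
        assert subs / aligned == pytest.approx(cfg.mismatch_rate, rel=0.20)
        assert dels / aligned == pytest.approx(cfg.deletion_rate, rel=0.20)
        assert ins / aligned == pytest.approx(cfg.insertion_rate, rel=0.20)

    def test_median_coverage_near_depth(self):
        cfg = small_config(chrom_sizes={"chr1": 150_000}, depth=30.0, read_median=15_000)
        genome, catalog = make_genome(cfg)
        truth_holder = __import__("tdnarray.simulate", fromlist=["TruthSet"]).TruthSet()
        reads = simulate_reads({"wildtype": genome}, cfg, truth_holder, rng_seed=3)
        cov = np.zeros(150_000)
        for rt in truth_holder.reads.values():
            cov[rt.start : rt.end] += 1
        # interior bins (edge bins are depleted by the sampling geometry)
        interior = cov[30_000:120_000]
        assert abs(np.median(interior) - 30) <= 3

    def test_low_quality_arm_is_second_encountered_in_both_directions(self):
        cfg = small_config()
        genome, catalog = make_genome(cfg)
        ev = EventSpec(
            kind="TDNA_ARRAY",
            chrom="chr1",
            position=20_000,
            units=[ArrayUnit(TDNA_ID, 3, 5_600, "+"), ArrayUnit(TDNA_ID, 120, 5_450, "-")],
        )
        mutant, truth = plant_events(genome, catalog, [ev], cfg)
        cfg2 = small_config(wt_allele_fraction=0.0, depth=40.0)
        reads = simulate_reads({"mutant": mutant}, cfg2, truth, rng_seed=8)
        ((a1s, a1e, a2s, a2e),) = truth.ir_arms["chr1"]
        n_checked = {"+": 0, "-": 0}
        for read in reads:
            rt = truth.reads[read.id]
            if rt.low_quality_arm is None:
                continue
            lo, hi = rt.low_quality_arm
            if rt.strand == "+":
                assert lo >= a2s and hi <= a2e  # later arm degraded
            else:
                assert lo >= a1s and hi <= a1e  # earlier template arm
            # the emitted qualities actually drop in that region
            frac0 = (lo - rt.start) / (rt.end - rt.start)
            frac1 = (hi - rt.start) / (rt.end - rt.start)
            if rt.strand == "-":
                frac0, frac1 = 1 - frac1, 1 - frac0
            q = np.asarray(read.quals, float)
            i0, i1 = int(frac0 * len(q)), int(frac1 * len(q))
            pad = (i1 - i0) // 5
            if i1 - i0 > 1000:
                assert q[i0 + pad : i1 - pad].mean() < 9.5
                n_checked[rt.strand] += 1
        assert n_checked["+"] >= 1 and n_checked["-"] >= 1


def _cigar_ops(cigar):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ("X" if ch == "X" else ch)
            num = ""


class TestScenarios:
    def test_all_seven_named_scenarios_exist(self):
        assert sorted(fixture_scenarios()) == [
            "canonical",
            "cpdna_filler",
            "eight_unit_array",
            "head_to_head",
            "inverted_duplication",
            "reciprocal_translocation",
            "tdna_free_fusion",
        ]

    def test_scenario_truth_complete(self):
        sc = simulate_scenario(
            "canonical", seed=1, config=small_config(chrom_sizes={"chr1": 150_000})
        )
        assert sc.truth.events and sc.truth.reads
        (ev,) = sc.truth.events
        assert ev.spec.target_deletion == 13
        assert all(rt.segments for rt in sc.truth.reads.values() if rt.haplotype == "mutant")
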