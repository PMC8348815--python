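import numpy as np
import pytest
from Bio import Align

from tdnarray.alignment import (
    ConfigurationError,
    ScoringScheme,
    build_index,
    chain_map,
    evalue,
    find_local_hits,
    smith_waterman,
    ungapped_lambda,
)
from tdnarray.records import SeqRecord, revcomp
from conftest import mutate, random_seq


def biopython_local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    # our gap of length L costs gap_open + L*gap_extend
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    return aligner.score(a, b)


def biopython_best_strand_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Best local score over both strands (the search space of the
    seed-and-extend aligner)."""
    return max(
        biopython_local_score(a, b, scheme),
        biopython_local_score(revcomp(a), b, scheme),
    )


class TestScoring:
    def test_lambda_satisfies_moment_equation(self):
        lam = ungapped_lambda(2, -3)
        assert abs(0.25 * np.exp(2 * lam) + 0.75 * np.exp(-3 * lam) - 1) < 1e-9

    def test_evalue_formula(self):
        scheme = ScoringScheme(karlin_K=0.5, karlin_lambda=1.0)
        e = evalue(20, 1000, 1000, scheme)
        assert e == pytest.approx(0.5e6 * np.exp(-20), rel=1e-9)
        assert e == pytest.approx(1.030e-3, rel=1e-3)

    def test_evalue_linear_in_db_len_and_monotone_in_score(self):
        scheme = ScoringScheme()
        assert evalue(20, 100, 2000, scheme) == pytest.approx(
            2 * evalue(20, 100, 1000, scheme)
        )
        assert evalue(40, 100, 1000, scheme) < evalue(20, 100, 1000, scheme)

    def test_evalue_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, ScoringScheme())

    def test_scheme_validation(self):
        with pytest.raises(ConfigurationError):
            ScoringScheme(match=-1)
        with pytest.raises(ConfigurationError):
            ScoringScheme(gap_open=1)


class TestIndex:
    def test_tiny_catalog_both_strands(self):
        idx = build_index({"s": "ACGTACGT"}, 8)
        # the single 8-mer is stored under its canonical form; looking the
        # sequence or its reverse complement up yields the same entry
        assert len(idx.lookup) == 1
        assert idx.total_len == 8

    def test_all_n_sequence_empty_index(self):
        idx = build_index({"s": "N" * 50}, 8)
        assert len(idx.lookup) == 0

    def test_k_out_of_range(self):
        with pytest.raises(ConfigurationError):
            build_index({"s": "ACGTACGT"}, 4)
        with pytest.raises(ConfigurationError):
            build_index({"s": "A" * 50}, 25)

    def test_empty_catalog(self):
        with pytest.raises(ConfigurationError):
            build_index({}, 13)


class TestFindLocalHits:
    def test_exact_substring(self, rng):
        sub = random_seq(rng, 5000)
        idx = build_index({"s": sub}, 13)
        q = SeqRecord("q", sub[1000:1500])
        (hit,) = find_local_hits(q, idx, max_evalue=1e6)
        assert (hit.q_start, hit.q_end) == (0, 500)
        assert (hit.s_start, hit.s_end) == (1000, 1500)
        assert hit.identity == 1.0 and hit.strand == "+"

    def test_reverse_complement_symmetry(self, rng):
        sub = random_seq(rng, 5000)
        idx = build_index({"s": sub}, 13)
        fwd = find_local_hits(SeqRecord("q", sub[1000:1500]), idx, max_evalue=1e6)
        rev = find_local_hits(
            SeqRecord("q", revcomp(sub[1000:1500])), idx, max_evalue=1e6
        )
        assert rev[0].strand == "-"
        assert (rev[0].s_start, rev[0].s_end) == (fwd[0].s_start, fwd[0].s_end)
        assert rev[0].score == fwd[0].score

    def test_uniform_25pct_mismatch_rejected_and_score_matches_oracle(self, rng):
        scheme = ScoringScheme()
        subject = random_seq(rng, 1000)
        frag = list(subject[300:600])
        for i in range(0, 300, 4):  # 25% of positions mutated
            frag[i] = "ACGT"[("ACGT".index(frag[i]) + 1) % 4]
        query = "".join(frag)
        idx = build_index({"s": subject}, 13)
        assert (
            find_local_hits(SeqRecord("q", query), idx, scheme, min_identity=0.80)
            == []
        )
        best = find_local_hits(
            SeqRecord("q", query),
            idx,
            scheme,
            min_identity=0.0,
            max_evalue=float("inf"),
            min_aln_len=1,
        )
        assert best[0].score == biopython_local_score(query, subject, scheme)

    def test_determinism(self, rng):
        sub = {"a": random_seq(rng, 3000), "b": random_seq(rng, 3000)}
        idx = build_index(sub, 13)
        q = SeqRecord("q", mutate(rng, sub["a"][500:1500]))
        h1 = find_local_hits(q, idx, max_evalue=1e6)
        h2 = find_local_hits(q, idx, max_evalue=1e6)
        assert h1 == h2

    def test_noisy_long_read_segments(self, rng):
        """An ONT-like chimeric read maps to all its source regions."""
        chrom = random_seq(rng, 30_000)
        tdna = random_seq(rng, 4_000)
        idx = build_index({"chrom": chrom, "tdna": tdna}, 13)
        true = chrom[2000:8000] + tdna[100:3900] + chrom[8013:14000]
        read = SeqRecord("r", mutate(rng, true))
        hits = find_local_hits(read, idx)
        subjects = sorted({h.subject_id for h in hits})
        assert subjects == ["chrom", "tdna"]
        tdna_hit = next(h for h in hits if h.subject_id == "tdna")
        assert abs(tdna_hit.s_start - 100) <= 20
        assert abs(tdna_hit.s_end - 3900) <= 20


class TestSmithWaterman:
    def test_against_biopython_random_pairs(self, rng):
        scheme = ScoringScheme()
        for _ in range(20):
            n = int(rng.integers(30, 400))
            a, b = random_seq(rng, n), random_seq(rng, int(rng.integers(30, 400)))
            if rng.random() < 0.5:
                b = b[:10] + a[5 : 5 + min(100, n - 5)] + b[10:]
            assert smith_waterman(a, b, scheme).score == biopython_local_score(
                a, b, scheme
            )


class TestChainMap:
    def test_interval_accuracy(self, rng):
        chrom = random_seq(rng, 40_000)
        idx = build_index({"chrom": chrom}, 13)
        read = SeqRecord("r", mutate(rng, chrom[5000:20000]))
        (m,) = chain_map(read, idx)
        assert abs(m.s_start - 5000) <= 50
        assert abs(m.s_end - 20000) <= 50

    def test_split_at_structural_junction(self, rng):
        chrom = random_seq(rng, 40_000)
        idx = build_index({"chrom": chrom}, 13)
        # 652 bp foreign insert: mapping must split, not bridge
        read = SeqRecord(
            "r",
            mutate(rng, chrom[5000:12000] + random_seq(rng, 652) + chrom[12010:19000]),
        )
        maps = chain_map(read, idx)
        assert len(maps) == 2
        ends = sorted((m.s_start, m.s_end) for m in maps)
        assert abs(ends[0][1] - 12000) <= 50 and abs(ends[1][0] - 12010) <= 50
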