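"""Scored local alignment: seed-and-extend with affine gaps and E-values.

This module stands in for a BLASTn search against the reference catalog.
Queries are seeded with exact k-mers (canonical form, both strands), seeds
are chained by diagonal proximity, and each chain is extended by a banded
affine-gap Smith-Waterman restricted to the chain's observed diagonal range
plus a fixed pad.  For small query x subject problems an exact full
Smith-Waterman pass supplements the heuristic, so the best reported hit on
small pairs is the true local optimum.

Hit significance is expressed as a Karlin-Altschul E-value
``E = K * m * n * exp(-lambda * S)``; lambda is derived numerically from the
scoring scheme, and E-values here serve as filter thresholds (the 1e-50
read-selection cutoff and the permissive short-match cutoff), not as
publishable statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .records import LocalHit, SeqRecord, revcomp

NEG_INF = np.int32(-(10**9) // 2)


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scoring

def ungapped_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 for uniform base frequencies."""
    if match <= 0 or mismatch >= 0:
        raise ConfigurationError("need match > 0 > mismatch")
    expected = 0.25 * match + 0.75 * mismatch
    if expected >= 0:
        raise ConfigurationError("expected score must be negative")

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 10.0))


@dataclass
class ScoringScheme:
    """Integer alignment scoring with Karlin-Altschul parameters.

    Defaults mirror megablast-style DNA scoring.  ``karlin_lambda`` is
    computed from the match/mismatch scores when not given; ``karlin_K``
    defaults to a conventional ungapped DNA value.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    karlin_K: float = 0.3
    karlin_lambda: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ConfigurationError("require match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ConfigurationError("gap penalties must be negative")
        if self.karlin_K <= 0:
            raise ConfigurationError("karlin_K must be positive")
        if self.karlin_lambda is None:
            self.karlin_lambda = ungapped_lambda(self.match, self.mismatch)
        if self.karlin_lambda <= 0:
            raise ConfigurationError("karlin_lambda must be positive")


def evalue(score: float, query_len: int, db_len: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation  E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    log_e = (
        np.log(scheme.karlin_K)
        + np.log(float(query_len))
        + np.log(float(db_len))
        - scheme.karlin_lambda * float(score)
    )
    # exp underflows to 0.0 for very strong scores, which is the right limit
    return float(np.exp(min(log_e, 700.0)))


# ---------------------------------------------------------------------------
# sequence encoding

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4 (never matches)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement k-mer integers plus validity mask."""
    n = len(codes)
    L = n - k + 1
    if L <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0, dtype=bool)
    c = codes.astype(np.int64)
    fwd = np.zeros(L, dtype=np.int64)
    rc = np.zeros(L, dtype=np.int64)
    for t in range(k):
        fwd = fwd * 4 + c[t : t + L]
        rc = rc * 4 + (3 - c[k - 1 - t : k - 1 - t + L])
    is_n = (codes == 4).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cum[k:] - cum[:-k]) == 0
    return fwd, rc, valid


# ---------------------------------------------------------------------------
# seed index

@dataclass
class SeedIndex:
    """Canonical k-mer index over the forward strands of a catalog.

    Each canonical k-mer maps to packed ``(subject, position, strand)``
    entries where strand records whether the subject's forward k-mer equals
    the canonical form (+) or its reverse complement (-).
    """

    k: int
    subject_ids: list[str]
    subject_seqs: dict[str, str]
    subject_codes: dict[str, np.ndarray]
    lookup: dict[int, list[int]]
    total_len: int

    def subject_len(self, sid: str) -> int:
        return len(self.subject_seqs[sid])


def build_index(
    catalog: Union[dict[str, str], Sequence[SeqRecord]], k: int = 13
) -> SeedIndex:
    """Index all catalog sequences with canonical k-mers (both strands)."""
    if not (8 <= k <= 21):
        raise ConfigurationError(f"k must be between 8 and 21, got {k}")
    if isinstance(catalog, dict):
        items = list(catalog.items())
    else:
        items = [(rec.id, rec.bases) for rec in catalog]
    if not items:
        raise ConfigurationError("empty catalog")

    subject_ids = [sid for sid, _ in items]
    subject_seqs = dict(items)
    subject_codes = {sid: encode(seq) for sid, seq in items}
    lookup: dict[int, list[int]] = {}
    total_len = 0
    for sidx, (sid, seq) in enumerate(items):
        total_len += len(seq)
        fwd, rc, valid = _kmer_values(subject_codes[sid], k)
        canonical = np.minimum(fwd, rc)
        strand_plus = fwd <= rc
        for pos in np.flatnonzero(valid):
            key = int(canonical[pos])
            packed = ((int(pos) * len(items) + sidx) << 1) | int(strand_plus[pos])
            lookup.setdefault(key, []).append(packed)
    return SeedIndex(k, subject_ids, subject_seqs, subject_codes, lookup, total_len)


# ---------------------------------------------------------------------------
# DP kernels (numba)

@njit(cache=True)
def _sw_full_kernel(q, s, match, mismatch, gap_open, gap_extend):
    n = len(q)
    m = len(s)
    NEG = -(10**9) // 2
    M = np.zeros((n + 1, m + 1), np.int32)
    X = np.full((n + 1, m + 1), NEG, np.int32)
    Y = np.full((n + 1, m + 1), NEG, np.int32)
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            prev = M[i - 1, j - 1]
            src = 1
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                src = 2
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                src = 3
            cand = prev + sub
            if prev <= 0:
                cand = sub
                src = 0
            if cand <= 0:
                M[i, j] = 0
                pM[i, j] = 0
            else:
                M[i, j] = cand
                pM[i, j] = src
                if cand > best:
                    best = cand
                    bi = i
                    bj = j
            op = M[i - 1, j] + gap_open + gap_extend
            ex = X[i - 1, j] + gap_extend
            if op >= ex:
                X[i, j] = op
                pX[i, j] = 1
            else:
                X[i, j] = ex
                pX[i, j] = 2
            op = M[i, j - 1] + gap_open + gap_extend
            ex = Y[i, j - 1] + gap_extend
            if op >= ex:
                Y[i, j] = op
                pY[i, j] = 1
            else:
                Y[i, j] = ex
                pY[i, j] = 2
    # traceback (best local alignments end in the match state)
    matches = 0
    aln_len = 0
    i = bi
    j = bj
    state = 1
    q0 = bi
    s0 = bj
    while i > 0 and j > 0:
        if state == 1:
            aln_len += 1
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                matches += 1
            p = pM[i, j]
            i -= 1
            j -= 1
            q0 = i
            s0 = j
            if p == 0:
                break
            state = p
        elif state == 2:
            aln_len += 1
            p = pX[i, j]
            i -= 1
            state = 1 if p == 1 else 2
        else:
            aln_len += 1
            p = pY[i, j]
            j -= 1
            state = 1 if p == 1 else 3
    return best, q0, bi, s0, bj, matches, aln_len


@njit(cache=True)
def _sw_banded_kernel(q, s, dlo, dhi, match, mismatch, gap_open, gap_extend):
    # band over diagonals d = j - i, d in [dlo, dhi]; score rows are
    # rolling buffers, only traceback pointers are kept per cell (packed
    # 2 bits per state into one byte) so memory is n x W bytes
    n = len(q)
    m = len(s)
    W = dhi - dlo + 1
    NEG = -(10**9) // 2
    M_prev = np.full(W, NEG, np.int32)
    X_prev = np.full(W, NEG, np.int32)
    Y_prev = np.full(W, NEG, np.int32)
    M_cur = np.full(W, NEG, np.int32)
    X_cur = np.full(W, NEG, np.int32)
    Y_cur = np.full(W, NEG, np.int32)
    ptr = np.zeros((n + 1, W), np.uint8)
    best = 0
    bi = 0
    bb = 0
    for i in range(0, n + 1):
        jlo = i + dlo
        if jlo < 0:
            jlo = 0
        jhi = i + dhi
        if jhi > m:
            jhi = m
        for b in range(W):
            M_cur[b] = NEG
            X_cur[b] = NEG
            Y_cur[b] = NEG
        for j in range(jlo, jhi + 1):
            b = j - i - dlo
            if i == 0 or j == 0:
                # boundary cells are fresh-start cells with score 0
                M_cur[b] = 0
                continue
            qi = q[i - 1]
            sub = match if (qi == s[j - 1] and qi < 4) else mismatch
            # diagonal predecessor (i-1, j-1) -> same band column
            prev = NEG
            src = 0
            if M_prev[b] > prev:
                prev = M_prev[b]
                src = 1
            if X_prev[b] > prev:
                prev = X_prev[b]
                src = 2
            if Y_prev[b] > prev:
                prev = Y_prev[b]
                src = 3
            if prev <= 0:
                cand = sub
                src = 0
            else:
                cand = prev + sub
            pm = 0
            if cand <= 0:
                M_cur[b] = 0
            else:
                M_cur[b] = cand
                pm = src
                if cand > best:
                    best = cand
                    bi = i
                    bb = b
            # vertical predecessor (i-1, j) -> band column b+1
            vm = NEG
            vx = NEG
            if b + 1 < W:
                vm = M_prev[b + 1]
                vx = X_prev[b + 1]
            op = vm + gap_open + gap_extend
            ex = vx + gap_extend
            px = 1
            if op >= ex:
                X_cur[b] = op
            else:
                X_cur[b] = ex
                px = 2
            # horizontal predecessor (i, j-1) -> band column b-1
            hm = NEG
            hy = NEG
            if b - 1 >= 0:
                hm = M_cur[b - 1]
                hy = Y_cur[b - 1]
            op = hm + gap_open + gap_extend
            ex = hy + gap_extend
            py = 1
            if op >= ex:
                Y_cur[b] = op
            else:
                Y_cur[b] = ex
                py = 2
            ptr[i, b] = pm | (px << 2) | (py << 4)
        tmp = M_prev
        M_prev = M_cur
        M_cur = tmp
        tmp = X_prev
        X_prev = X_cur
        X_cur = tmp
        tmp = Y_prev
        Y_prev = Y_cur
        Y_cur = tmp
    # traceback
    matches = 0
    aln_len = 0
    i = bi
    b = bb
    bj = bi + dlo + bb
    j = bj
    state = 1
    q0 = bi
    s0 = bj
    while i > 0 and j > 0:
        code = ptr[i, b]
        if state == 1:
            aln_len += 1
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                matches += 1
            p = code & 3
            i -= 1
            j -= 1
            q0 = i
            s0 = j
            if p == 0:
                break
            state = p
        elif state == 2:
            aln_len += 1
            p = (code >> 2) & 3
            i -= 1
            b += 1
            state = 1 if p == 1 else 2
        else:
            aln_len += 1
            p = (code >> 4) & 3
            j -= 1
            b -= 1
            state = 1 if p == 1 else 3
    return best, q0, bi, s0, bj, matches, aln_len


@dataclass
class Alignment:
    """Result of a pairwise local alignment (coords 0-based half-open)."""

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    aln_len: int

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len if self.aln_len else 0.0


def smith_waterman(query: str, subject: str, scheme: Optional[ScoringScheme] = None) -> Alignment:
    """Exact affine-gap local alignment (full DP) on the forward strands."""
    scheme = scheme or ScoringScheme()
    res = _sw_full_kernel(
        encode(query),
        encode(subject),
        scheme.match,
        scheme.mismatch,
        scheme.gap_open,
        scheme.gap_extend,
    )
    return Alignment(*[int(x) for x in res])


# ---------------------------------------------------------------------------
# chaining

@dataclass
class _Chain:
    q_first: int
    q_last: int
    s_first: int
    s_last: int
    d_min: int
    d_max: int
    n_seeds: int


def _chain_seeds(
    qpos: np.ndarray,
    spos: np.ndarray,
    max_diag_diff: int = 100,
    max_seed_gap: int = 1000,
) -> list[_Chain]:
    """Greedy co-linear chaining of (query, subject) seed positions."""
    order = np.lexsort((spos, qpos))
    chains: list[_Chain] = []
    for idx in order:
        qp = int(qpos[idx])
        sp = int(spos[idx])
        d = sp - qp
        placed = False
        for ch in reversed(chains):
            if (
                qp >= ch.q_last
                and sp >= ch.s_last
                and ch.d_min - max_diag_diff <= d <= ch.d_max + max_diag_diff
                and qp - ch.q_last <= max_seed_gap
            ):
                ch.q_last = qp
                ch.s_last = sp
                ch.d_min = min(ch.d_min, d)
                ch.d_max = max(ch.d_max, d)
                ch.n_seeds += 1
                placed = True
                break
        if not placed:
            chains.append(_Chain(qp, qp, sp, sp, d, d, 1))
    return _merge_colinear_chains(chains)


def _merge_colinear_chains(
    chains: list[_Chain],
    diag_tol: int = 500,
    max_gap: int = 300,
) -> list[_Chain]:
    """Second-level chaining: rejoin chains split by accumulated indel drift.

    Long ONT alignments drift across more diagonals than the strict
    seeding tolerance; without rejoining, one homologous region yields two
    overlapping hits and the downstream overlap rule discards one.  Chains
    merge only when they effectively abut (or overlap) on BOTH query and
    subject and sit within ``diag_tol`` diagonals: a genuine structural
    changeover (junction filler, target-site deletion insert) leaves
    unmatched query sequence between the chains and is preserved.
    """
    chains = sorted(chains, key=lambda c: (c.q_first, c.s_first))
    out: list[_Chain] = []
    for ch in chains:
        merged = False
        for prev in out:
            if (
                ch.q_first >= prev.q_first
                and ch.s_first >= prev.s_first
                and ch.q_first - prev.q_last <= max_gap
                and ch.s_first - prev.s_last <= max_gap
                and prev.d_min - diag_tol <= ch.d_min
                and ch.d_max <= prev.d_max + diag_tol
            ):
                prev.q_last = max(prev.q_last, ch.q_last)
                prev.s_last = max(prev.s_last, ch.s_last)
                prev.q_first = min(prev.q_first, ch.q_first)
                prev.s_first = min(prev.s_first, ch.s_first)
                prev.d_min = min(prev.d_min, ch.d_min)
                prev.d_max = max(prev.d_max, ch.d_max)
                prev.n_seeds += ch.n_seeds
                merged = True
                break
        if not merged:
            out.append(ch)
    return out


# ---------------------------------------------------------------------------
# find_local_hits

def _extend_chain(
    wq_codes: np.ndarray,
    s_codes: np.ndarray,
    chain: _Chain,
    k: int,
    scheme: ScoringScheme,
    pad: int = 400,
    band_pad: int = 150,
    max_band: int = 4000,
) -> Optional[Alignment]:
    qlen = len(wq_codes)
    slen = len(s_codes)
    qa = max(0, chain.q_first - pad)
    qb = min(qlen, chain.q_last + k + pad)
    sa = max(0, chain.s_first - pad)
    sb = min(slen, chain.s_last + k + pad)
    # diagonals in window coordinates
    dlo = (chain.d_min - (sa - qa)) - band_pad
    dhi = (chain.d_max - (sa - qa)) + band_pad
    if dhi - dlo + 1 > max_band:
        centre = (dlo + dhi) // 2
        dlo = centre - max_band // 2
        dhi = centre + max_band // 2
    dlo = max(dlo, -(qb - qa))
    dhi = min(dhi, sb - sa)
    if dhi < dlo:
        return None
    res = _sw_banded_kernel(
        wq_codes[qa:qb],
        s_codes[sa:sb],
        int(dlo),
        int(dhi),
        scheme.match,
        scheme.mismatch,
        scheme.gap_open,
        scheme.gap_extend,
    )
    score, q0, q1, s0, s1, matches, aln_len = [int(x) for x in res]
    if score <= 0 or aln_len == 0:
        return None
    return Alignment(score, qa + q0, qa + q1, sa + s0, sa + s1, matches, aln_len)


def _hit_sort_key(h: LocalHit):
    return (-h.score, h.subject_id, h.s_start, h.q_start)


def find_local_hits(
    query: SeqRecord,
    index: SeedIndex,
    scoring: Optional[ScoringScheme] = None,
    min_identity: float = 0.80,
    max_evalue: float = 1e-50,
    min_aln_len: int = 50,
    exact_max_cells: int = 4_000_000,
    max_diag_diff: int = 100,
    max_seed_gap: int = 1000,
    min_chain_seeds: int = 3,
) -> list[LocalHit]:
    """All local hits of ``query`` against the indexed catalog.

    Hits satisfy all three thresholds, are merged to the best-scoring
    representative when redundant (same subject/strand, mutually overlapping
    query and subject intervals), and are returned sorted by decreasing
    score with deterministic tie-breaking.
    """
    scoring = scoring or ScoringScheme()
    qlen = len(query.bases)
    k = index.k
    if qlen < k:
        raise ValueError(f"query {query.id} shorter than k={k}")
    q_codes = encode(query.bases)
    rq_codes = encode(revcomp(query.bases))
    fwd, rc, valid = _kmer_values(q_codes, k)
    canonical = np.minimum(fwd, rc)
    q_is_canon = fwd <= rc
    n_sub = len(index.subject_ids)

    # seed matches bucketed by (subject_idx, relative strand)
    buckets: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for qp in np.flatnonzero(valid):
        entries = index.lookup.get(int(canonical[qp]))
        if not entries:
            continue
        qp = int(qp)
        for packed in entries:
            s_canon = packed & 1
            rest = packed >> 1
            sidx = rest % n_sub
            sp = rest // n_sub
            # same canonical orientation on query and subject -> forward match
            plus = (s_canon == 1) == bool(q_is_canon[qp])
            if plus:
                buckets.setdefault((sidx, 0), []).append((qp, sp))
            else:
                # position of this k-mer on the reverse-complemented query
                buckets.setdefault((sidx, 1), []).append((qlen - k - qp, sp))

    raw_hits: list[LocalHit] = []

    def _emit(aln: Alignment, sidx: int, minus: bool) -> None:
        if aln.aln_len < 1:
            return
        sid = index.subject_ids[sidx]
        if minus:
            q_start = qlen - aln.q_end
            q_end = qlen - aln.q_start
            strand = "-"
        else:
            q_start, q_end = aln.q_start, aln.q_end
            strand = "+"
        if q_end <= q_start or aln.s_end <= aln.s_start:
            return
        raw_hits.append(
            LocalHit(
                query_id=query.id,
                q_start=q_start,
                q_end=q_end,
                strand=strand,
                subject_id=sid,
                s_start=aln.s_start,
                s_end=aln.s_end,
                identity=aln.identity,
                score=aln.score,
                evalue=evalue(aln.score, qlen, index.total_len, scoring),
                aln_len=aln.aln_len,
            )
        )

    for (sidx, minus), pairs in buckets.items():
        sid = index.subject_ids[sidx]
        s_codes = index.subject_codes[sid]
        wq = rq_codes if minus else q_codes
        arr = np.asarray(pairs, dtype=np.int64)
        chains = _chain_seeds(arr[:, 0], arr[:, 1], max_diag_diff, max_seed_gap)
        for ch in chains:
            if ch.n_seeds < min_chain_seeds:
                continue
            aln = _extend_chain(wq, s_codes, ch, k, scoring)
            if aln is not None:
                _emit(aln, sidx, bool(minus))

    # exact supplement for small problems: guarantees the optimum is reported
    for sidx, sid in enumerate(index.subject_ids):
        slen = index.subject_len(sid)
        if qlen * slen > exact_max_cells:
            continue
        best_existing = max(
            (h.score for h in raw_hits if h.subject_id == sid), default=0
        )
        s_codes = index.subject_codes[sid]
        for minus, wq in ((False, q_codes), (True, rq_codes)):
            res = _sw_full_kernel(
                wq,
                s_codes,
                scoring.match,
                scoring.mismatch,
                scoring.gap_open,
                scoring.gap_extend,
            )
            aln = Alignment(*[int(x) for x in res])
            if aln.score > best_existing and aln.aln_len >= 1:
                _emit(aln, sidx, minus)

    # thresholds
    hits = [
        h
        for h in raw_hits
        if h.identity >= min_identity
        and h.evalue <= max_evalue
        and h.aln_len >= min_aln_len
    ]

    # merge redundant hits: same subject+strand, mutually overlapping
    hits.sort(key=_hit_sort_key)
    kept: list[LocalHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            if g.subject_id != h.subject_id or g.strand != h.strand:
                continue
            q_ov = min(g.q_end, h.q_end) - max(g.q_start, h.q_start)
            s_ov = min(g.s_end, h.s_end) - max(g.s_start, h.s_start)
            min_q = min(g.q_end - g.q_start, h.q_end - h.q_start)
            min_s = min(g.s_end - g.s_start, h.s_end - h.s_start)
            if q_ov > 0.5 * min_q and s_ov > 0.5 * min_s:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def count_seed_matches(query: SeqRecord, index: SeedIndex, stride: int = 4) -> int:
    """Cheap pre-filter: number of strided query k-mers present in the index.

    A genuine >=50 bp match at ONT error rates leaves several exact
    k-mers, so reads with fewer than a couple of matches cannot produce a
    passing hit and need no alignment work.
    """
    codes = encode(query.bases)
    fwd, rc, valid = _kmer_values(codes, index.k)
    canonical = np.minimum(fwd, rc)
    lookup = index.lookup
    n = 0
    for qp in range(0, len(canonical), stride):
        if valid[qp] and int(canonical[qp]) in lookup:
            n += 1
    return n


# ---------------------------------------------------------------------------
# chain-only mapping (interval evidence for coverage / AEF / zygosity)

@dataclass
class ChainMapping:
    """A read-to-reference mapping derived from a seed chain (no DP)."""

    query_id: str
    q_start: int
    q_end: int
    strand: str
    subject_id: str
    s_start: int
    s_end: int
    n_seeds: int


def chain_map(
    query: SeqRecord,
    index: SeedIndex,
    min_chain_seeds: int = 5,
    min_span: int = 200,
    max_diag_diff: int = 100,
    max_seed_gap: int = 1000,
) -> list[ChainMapping]:
    """Approximate mapping intervals from seed chains alone.

    Used where only interval-level evidence is needed (binned coverage,
    alignment-end pileups, spanning-read counts); endpoints are accurate to
    roughly the seed length, well inside a 100 bp bin.
    """
    qlen = len(query.bases)
    k = index.k
    if qlen < k:
        return []
    q_codes = encode(query.bases)
    fwd, rc, valid = _kmer_values(q_codes, k)
    canonical = np.minimum(fwd, rc)
    q_is_canon = fwd <= rc
    n_sub = len(index.subject_ids)
    buckets: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for qp in np.flatnonzero(valid):
        entries = index.lookup.get(int(canonical[qp]))
        if not entries:
            continue
        qp = int(qp)
        for packed in entries:
            s_canon = packed & 1
            rest = packed >> 1
            sidx = rest % n_sub
            sp = rest // n_sub
            plus = (s_canon == 1) == bool(q_is_canon[qp])
            if plus:
                buckets.setdefault((sidx, 0), []).append((qp, sp))
            else:
                buckets.setdefault((sidx, 1), []).append((qlen - k - qp, sp))
    out: list[ChainMapping] = []
    for (sidx, minus), pairs in buckets.items():
        arr = np.asarray(pairs, dtype=np.int64)
        for ch in _chain_seeds(arr[:, 0], arr[:, 1], max_diag_diff, max_seed_gap):
            if ch.n_seeds < min_chain_seeds:
                continue
            if ch.s_last + k - ch.s_first < min_span:
                continue
            if minus:
                q_start = qlen - (ch.q_last + k)
                q_end = qlen - ch.q_first
                strand = "-"
            else:
                q_start, q_end = ch.q_first, ch.q_last + k
                strand = "+"
            out.append(
                ChainMapping(
                    query_id=query.id,
                    q_start=q_start,
                    q_end=q_end,
                    strand=strand,
                    subject_id=index.subject_ids[sidx],
                    s_start=ch.s_first,
                    s_end=ch.s_last + k,
                    n_seeds=ch.n_seeds,
                )
            )
    out.sort(key=lambda m: (m.subject_id, m.s_start, m.q_start))
    return out
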