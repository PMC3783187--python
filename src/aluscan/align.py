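"""Local alignment primitives.

The pipeline's internal aligner contract: Smith–Waterman local alignment with
match +1, mismatch −2, gap open −4, gap extend −1 (a length-k gap costs
4 + (k−1)), and a mapping-quality surrogate equal to the difference between
the best and second-best locus scores, clamped to [0, 60].

The row-wise DP is exact affine-gap Gotoh.  The horizontal (target-gap) state
is vectorised with a prefix-max scan: because gap-open >= gap-extend, a gap
opening out of the E state is always dominated by extending the original gap,
so E[j] = max_k<=j-1 (H0[k] − open − (j−1−k)·ext) where H0 excludes E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = 4      # cost of the first gapped base (positive)
    gap_extend: int = 1    # cost of each further gapped base (positive)


DEFAULT_SCORING = Scoring()
NEG = -(10 ** 6)


def _sub_row(qc: int, t: np.ndarray, sc: Scoring) -> np.ndarray:
    """Substitution scores of one query base against the whole target."""
    s = np.where(t == qc, sc.match, sc.mismatch)
    # windows touching N never score as matches
    if qc == 4:
        s[:] = sc.mismatch
    else:
        s[t == 4] = sc.mismatch
    return s


def sw_rows(query: np.ndarray, target: np.ndarray,
            sc: Scoring = DEFAULT_SCORING, local: bool = True):
    """Run the DP, returning per-row maxima and their target columns.

    Returns ``(row_best, row_arg, H_last)`` where ``row_best[i]`` is the best
    score of an alignment consuming exactly ``query[:i]`` at its read end
    (``i`` in 0..n) and ``row_arg[i]`` the leftmost target *end* position
    achieving it.  With ``local=True`` the alignment may start anywhere in
    both sequences (score floor 0); with ``local=False`` every query base
    from the start of the row range must be consumed (query-global, target
    free at both ends).
    """
    n, m = len(query), len(target)
    ext, opn = sc.gap_extend, sc.gap_open
    # E[j] = max_{k<=j-1}(H0[k] + ext*k) - open - ext*(j-1)
    jpen = opn + ext * (np.arange(m + 1, dtype=np.int64) - 1)

    H = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, NEG, dtype=np.int64)
    if not local:
        # leading target-gap row: query base 0 not yet consumed, H[0][j]=0
        pass
    row_best = np.empty(n + 1, dtype=np.int64)
    row_arg = np.empty(n + 1, dtype=np.int64)
    row_best[0] = 0
    row_arg[0] = 0
    karr = ext * np.arange(m + 1, dtype=np.int64)

    for i in range(1, n + 1):
        sub = _sub_row(int(query[i - 1]), target, sc)
        diag = H[:-1] + sub
        F = np.maximum(F - ext, H - opn)
        H0 = np.empty(m + 1, dtype=np.int64)
        if local:
            H0[0] = 0
            H0[1:] = np.maximum(diag, F[1:])
            np.maximum(H0, 0, out=H0)
        else:
            H0[0] = F[0]
            H0[1:] = np.maximum(diag, F[1:])
        # E via prefix-max scan over H0
        P = np.maximum.accumulate(H0 + karr)
        E = np.empty(m + 1, dtype=np.int64)
        E[0] = NEG
        E[1:] = P[:-1] - jpen[1:]
        H = np.maximum(H0, E)
        row_best[i] = H.max()
        row_arg[i] = int(H.argmax())
    return row_best, row_arg, H


def sw_local(query_s: str, target_s: str, sc: Scoring = DEFAULT_SCORING):
    """Best local alignment; returns (score, q_start, q_end, t_start, t_end).

    Endpoints are 0-based half-open on query and target.  Ties resolve to the
    smallest query end, then leftmost target end.  Returns score 0 and empty
    intervals when nothing aligns.
    """
    q, t = encode(query_s), encode(target_s)
    row_best, row_arg, _ = sw_rows(q, t, sc, local=True)
    score = int(row_best.max())
    if score <= 0:
        return 0, 0, 0, 0, 0
    q_end = int(row_best.argmax())
    t_end = int(row_arg[q_end])
    # recover the start by aligning the reversed prefixes
    rq = q[:q_end][::-1]
    rt = t[:t_end][::-1]
    rb, ra, _ = sw_rows(rq, rt, sc, local=True)
    rq_end = int(rb.argmax())
    rt_end = int(ra[rq_end])
    return score, q_end - rq_end, q_end, t_end - rt_end, t_end


def prefix_table(query: np.ndarray, target: np.ndarray,
                 sc: Scoring = DEFAULT_SCORING):
    """A[i] = best score of a local alignment of query[:i] ending exactly at
    read position i (read start free / soft-clipped); arg[i] = leftmost
    target end column."""
    row_best, row_arg, _ = sw_rows(query, target, sc, local=True)
    return row_best, row_arg


def suffix_table(query: np.ndarray, target: np.ndarray,
                 sc: Scoring = DEFAULT_SCORING):
    """B[j] = best score of a local alignment of query[j:] starting exactly at
    read position j (read end free); arg[j] = leftmost target *start* column
    among optima of the reversed problem's leftmost tie."""
    n, m = len(query), len(target)
    rb, ra, _ = sw_rows(query[::-1], target[::-1], sc, local=True)
    B = rb[::-1].copy()
    Barg = (m - ra)[::-1].copy()
    return B, Barg


def global_query_rows(query: np.ndarray, target: np.ndarray,
                      sc: Scoring = DEFAULT_SCORING):
    """mid[r] = best score aligning query[:r] with *every* query base
    consumed (gaps allowed), target-local.  Used for the middle segment of a
    two-junction split alignment."""
    row_best, row_arg, _ = sw_rows(query, target, sc, local=False)
    return row_best, row_arg


# ---------------------------------------------------------------------------
# Seed-and-extend read mapping against a genome
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index over a genome for seed-and-extend local mapping.

    Mapping success requires the local alignment to cover at least
    ``min_cover`` of the read and score at least ``min_score``.  The MAPQ
    surrogate is best-minus-second-best locus score clamped to [0, 60].
    """

    def __init__(self, genome, k: int = 16, min_score: int = 20,
                 min_cover: float = 0.95, sc: Scoring = DEFAULT_SCORING):
        self.genome = genome
        self.k = k
        self.min_score = min_score
        self.min_cover = min_cover
        self.sc = sc
        self.chrom_names: list[str] = []
        self.offsets: list[int] = []
        parts = []
        off = 0
        for rec in genome:
            self.chrom_names.append(rec.name)
            self.offsets.append(off)
            parts.append(rec.seq)
            off += len(rec.seq)
        self.cat = "".join(parts)
        self.total = off
        enc = encode(self.cat).astype(np.uint64)
        n_kmers = self.total - k + 1
        if n_kmers <= 0:
            raise ValueError("genome shorter than k")
        codes = np.zeros(n_kmers, dtype=np.uint64)
        valid = np.ones(n_kmers, dtype=bool)
        for l in range(k):
            b = enc[l:l + n_kmers]
            codes = codes * np.uint64(4) + np.where(b == 4, 0, b)
            valid &= b != 4
        # mask k-mers spanning chromosome boundaries
        for o in self.offsets[1:]:
            valid[max(0, o - k + 1):o] = False
        self.positions = np.nonzero(valid)[0].astype(np.int64)
        kept = codes[valid]
        order = np.argsort(kept, kind="stable")
        self.sorted_codes = kept[order]
        self.sorted_pos = self.positions[order]

    def _to_chrom(self, gpos: int) -> tuple[str, int]:
        idx = np.searchsorted(np.asarray(self.offsets), gpos, side="right") - 1
        return self.chrom_names[idx], gpos - self.offsets[idx]

    def _kmer_code(self, seq: str, i: int) -> int | None:
        sub = seq[i:i + self.k]
        if "N" in sub:
            return None
        code = 0
        for ch in sub:
            code = code * 4 + int(_ENC[ord(ch)])
        return code

    def _seed_hits(self, seq: str, max_hits_per_seed: int = 64):
        stride = max(1, self.k // 2)
        diags: dict[int, int] = {}
        starts = list(range(0, max(1, len(seq) - self.k + 1), stride))
        tail = len(seq) - self.k
        if tail > 0 and tail not in starts:
            starts.append(tail)
        for i in starts:
            code = self._kmer_code(seq, i)
            if code is None:
                continue
            lo = np.searchsorted(self.sorted_codes, code, side="left")
            hi = np.searchsorted(self.sorted_codes, code, side="right")
            if hi - lo == 0 or hi - lo > max_hits_per_seed:
                continue
            for p in self.sorted_pos[lo:hi]:
                d = int(p) - i
                diags[d] = diags.get(d, 0) + 1
        return diags

    def map_read(self, seq: str, max_loci: int = 8):
        """Best local mapping of ``seq`` (either strand) or None.

        Returns a dict with chrom, pos (0-based), strand, score, mapq,
        q_start, q_end (on the given sequence's forward orientation after
        strand normalisation).
        """
        cands = []
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            diags = self._seed_hits(s)
            for d, votes in sorted(diags.items(), key=lambda kv: -kv[1])[:max_loci]:
                cands.append((strand, s, d, votes))
        results = []
        seen_windows = set()
        for strand, s, d, _ in cands:
            w0 = max(0, d - 30)
            w1 = min(self.total, d + len(s) + 30)
            key = (strand, w0 // 20)
            if key in seen_windows:
                continue
            seen_windows.add(key)
            score, qs, qe, ts, te = sw_local(s, self.cat[w0:w1], self.sc)
            results.append((score, strand, s, qs, qe, w0 + ts, w0 + te))
        if not results:
            return None
        results.sort(key=lambda r: (-r[0], r[5]))
        best = results[0]
        second = 0
        for r in results[1:]:
            # a distinct locus, not a jittered window of the same one
            if r[1] != best[1] or abs(r[5] - best[5]) > len(seq):
                second = r[0]
                break
        score, strand, s, qs, qe, gts, gte = best
        if score < self.min_score or (qe - qs) < self.min_cover * len(seq):
            return None
        mapq = max(0, min(60, score - second))
        chrom, pos = self._to_chrom(gts)
        return {
            "chrom": chrom, "pos": pos, "strand": strand, "score": score,
            "mapq": mapq, "q_start": qs, "q_end": qe, "seq_oriented": s,
        }


def quick_local_score(seq: str, target: str,
                      sc: Scoring = DEFAULT_SCORING) -> tuple[int, int]:
    """Best local alignment score and leftmost target end (no traceback)."""
    rb, ra, _ = sw_rows(encode(seq), encode(target), sc, local=True)
    i = int(rb.argmax())
    return int(rb[i]), int(ra[i])


def best_consensus_hit(seq: str, consensus: str,
                       sc: Scoring = DEFAULT_SCORING):
    """Best local alignment of a read against one consensus, both strands.

    Returns (score, strand, cons_start, cons_end) with consensus
    coordinates on the + (consensus-forward) strand, 0-based half-open.
    The end column is exact; the start is a cheap lower-bound estimate
    (end minus read length) — the evidence screen needs score and strand
    only, and precise consensus footprints are recomputed during split
    mapping.
    """
    fs, fe = quick_local_score(seq, consensus, sc)
    rs, re_ = quick_local_score(revcomp(seq), consensus, sc)
    if fs >= rs:
        return fs, "+", max(0, fe - len(seq)), fe
    # reverse-strand hit: report the footprint on the + consensus strand
    return rs, "-", max(0, re_ - len(seq)), re_
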