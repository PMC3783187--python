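"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: plain-Python Gotoh DPs and explicit
enumeration over split points, kept free of the production code paths in
``aluscan.align`` / ``aluscan.splitmap``.
"""

MATCH, MISMATCH, OPEN, EXT = 1, -2, 4, 1
NEG = -(10 ** 9)


def scalar_local_rows(q: str, t: str):
    """Per-row maxima of a scalar local Gotoh DP.

    Returns A with A[i] = best score of a local alignment whose query part
    ends exactly at position i (A[0] = 0).
    """
    n, m = len(q), len(t)
    Hprev = [0] * (m + 1)
    Fprev = [NEG] * (m + 1)
    A = [0] * (n + 1)
    for i in range(1, n + 1):
        H = [0] * (m + 1)
        F = [0] * (m + 1)
        E = NEG
        qc = q[i - 1]
        best = 0
        for j in range(m + 1):
            F[j] = max(Fprev[j] - EXT, Hprev[j] - OPEN)
            if j > 0:
                E = max(E - EXT, H[j - 1] - OPEN)
                sub = MATCH if qc == t[j - 1] else MISMATCH
                H[j] = max(0, Hprev[j - 1] + sub, E, F[j])
            else:
                E = NEG
                H[j] = max(0, F[j])
            if H[j] > best:
                best = H[j]
        A[i] = best
        Hprev, Fprev = H, F
    return A


def scalar_local_score(q: str, t: str) -> int:
    return max(scalar_local_rows(q, t))


def scalar_global_query_rows(q: str, t: str):
    """mid[r] = best score aligning ALL of q[:r] (gaps allowed), locally
    in t; mid[0] = 0."""
    n, m = len(q), len(t)
    Hprev = [0] * (m + 1)
    Fprev = [NEG] * (m + 1)
    mids = [0] * (n + 1)
    for i in range(1, n + 1):
        H = [0] * (m + 1)
        F = [0] * (m + 1)
        E = NEG
        qc = q[i - 1]
        for j in range(m + 1):
            F[j] = max(Fprev[j] - EXT, Hprev[j] - OPEN)
            if j > 0:
                E = max(E - EXT, H[j - 1] - OPEN)
                sub = MATCH if qc == t[j - 1] else MISMATCH
                H[j] = max(Hprev[j - 1] + sub, E, F[j])
            else:
                E = NEG
                H[j] = F[j]
        mids[i] = max(H)
        Hprev, Fprev = H, F
    return mids


def scalar_global_query(q: str, t: str) -> int:
    """Best score aligning ALL of q (gaps allowed), locally in t."""
    return scalar_global_query_rows(q, t)[len(q)]


def split_score_oracle(read: str, window: str, cons: str,
                       anchor_min: int = 8) -> int:
    """Enumerate every split point / split-point pair of the read.

    Pieces: reference prefix ending at read position i (local start), a
    consensus piece, and/or a reference suffix starting at read position j
    (local end); the two-jump middle consumes every read base in [i, j).
    Every piece must score >= anchor_min.  Mirrors the documented
    split-alignment objective by direct enumeration.
    """
    n = len(read)
    A = scalar_local_rows(read, window)
    B = scalar_local_rows(read[::-1], window[::-1])[::-1]
    Ac = scalar_local_rows(read, cons)
    Bc = scalar_local_rows(read[::-1], cons[::-1])[::-1]
    best = max(A)                      # reference only
    ca = max(Ac)
    if ca >= anchor_min:
        best = max(best, ca)           # consensus only
    for i in range(n + 1):
        if A[i] >= anchor_min and Bc[i] >= anchor_min:
            best = max(best, A[i] + Bc[i])
        if Ac[i] >= anchor_min and B[i] >= anchor_min:
            best = max(best, Ac[i] + B[i])
    for i in range(n + 1):
        if A[i] < anchor_min:
            continue
        mids = scalar_global_query_rows(read[i:], cons)
        for j in range(i + anchor_min, n + 1):
            if B[j] < anchor_min:
                continue
            mid = mids[j - i]
            if mid >= anchor_min:
                best = max(best, A[i] + mid + B[j])
    return best


def binom_tail_enumeration(n: int, p: float, obs: int, upper: bool) -> float:
    """Exact binomial tail by summing the pmf term by term (n small)."""
    from math import comb
    ks = range(obs, n + 1) if upper else range(0, obs + 1)
    return sum(comb(n, k) * p ** k * (1 - p) ** (n - k) for k in ks)


def count_6mers_naive(seq: str):
    """Both-strand 6mer counting by direct string scan."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = seq.translate(comp)[::-1]
    counts: dict[str, int] = {}
    for strand in (seq, rc):
        for i in range(len(strand) - 5):
            w = strand[i:i + 6]
            if "N" not in w:
                counts[w] = counts.get(w, 0) + 1
    return counts


def clusters_by_transitive_closure(intervals):
    """Single-linkage clustering by repeated merging (quadratic, obvious)."""
    groups = [[iv] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(x[0] == y[0] and x[1] < y[2] and y[1] < x[2]
                       for x in groups[a] for y in groups[b]):
                    groups[a].extend(groups.pop(b))
                    changed = True
                    break
            if changed:
                break
    return groups
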