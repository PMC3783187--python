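"""Split mapping: cluster candidate fragments, align each read allowing
jumps between the reference window and an Alu consensus, and build calls
with breakpoints, TSD lengths and confidence intervals.

Split-alignment objective.  A read may be interpreted as (a) reference
only; (b) one jump reference->consensus or consensus->reference; (c) two
jumps reference->consensus->reference (read spans the whole insertion); or
(d) consensus only (read wholly inside the element).  Jump points partition
the read; the outer pieces are locally aligned with a free (soft-clipped)
outer end and anchored at the jump point, the middle piece of (c) consumes
every read base between its jumps (consensus-local).  Each piece must score
at least ``anchor_min`` (with match = +1 this forces >= anchor_min matched
bases), which suppresses spurious 1-base jumps.  Because of the TSD, the
reference->consensus junction is the insertion *start* (right end of the
TSD) and the consensus->reference junction the insertion *end* (left end of
the TSD); for a standard insertion the end junction lies upstream of the
start junction and their difference is the TSD length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import (
    DEFAULT_SCORING,
    Scoring,
    encode,
    global_query_rows,
    prefix_table,
    revcomp,
    suffix_table,
    sw_local,
)
from .models import MAXTSD, AluCallRecord
from .evidence import CandidateFragment, PairingProfile

#: minimum score (= matched bases) per split-alignment segment
ANCHOR_MIN = 8
#: maximum reference window length for the split DP
WINDOW_MAX = 5000


class WindowTooLarge(ValueError):
    pass


@dataclass
class Cluster:
    chrom: str
    window_start: int
    window_end: int
    members: list[CandidateFragment]
    consensus: str = ""
    strand: str = "+"
    implied: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SplitAlignment:
    read_name: str
    config: str                 # ref | cons | ref_cons | cons_ref | ref_cons_ref
    score_split: int
    score_ref_only: int
    junctions: list = field(default_factory=list)  # (side, ref_pos)
    cons_interval: tuple | None = None             # 0-based on + consensus

    @property
    def has_alu(self) -> bool:
        return self.config != "ref"


@dataclass
class ClusterSummary:
    cluster: Cluster
    score_alu: float
    score_null: float
    supp: int
    inner_min: int
    inner_max: int
    bp_start: int | None
    bp_end: int | None
    reads_left: int
    reads_right: int


def implied_interval(cand: CandidateFragment, profile: PairingProfile,
                     clip_min: int = 10) -> tuple[str, int, int] | None:
    """Reference interval where the fragment implies an insertion locus.

    Clipped anchors pin the junction near the clip point; otherwise the
    insertion lies on the anchor's 3' side within the fragment span.
    """
    mapped = [r for r in cand.template.reads if r.is_mapped]
    if not mapped:
        return None
    anchor = max(mapped, key=lambda r: (r.mapq, -r.pos))
    frag_max = profile.frag_max if profile.is_paired else \
        2 * max(len(r.seq) for r in cand.template.reads)
    if anchor.clip_right >= clip_min and anchor.clip_right >= anchor.clip_left:
        j = anchor.end
        return anchor.chrom, j - MAXTSD, j + MAXTSD
    if anchor.clip_left >= clip_min:
        j = anchor.pos
        return anchor.chrom, j - MAXTSD, j + MAXTSD
    if anchor.strand == "+":
        return anchor.chrom, anchor.end, anchor.pos + frag_max
    return anchor.chrom, anchor.end - frag_max, anchor.pos


def cluster_fragments(candidates, profiles,
                      window_max: int = WINDOW_MAX) -> list[Cluster]:
    """Single-linkage clustering of implied insertion intervals.

    Fragments merge when their implied intervals overlap on the same
    chromosome; clusters need >= 2 members and at least one consensus hit.
    The cluster consensus (and its strand) is the entry with the highest
    summed hit score over members — chosen once per cluster for determinism.
    """
    items = []
    for cand in candidates:
        if not cand.alu_hits:
            continue
        profile = profiles.get(cand.template.read_group)
        if profile is None:
            continue
        iv = implied_interval(cand, profile)
        if iv is None:
            continue
        items.append((iv[0], iv[1], iv[2], cand))
    items.sort(key=lambda x: (x[0], x[1], x[2]))
    clusters: list[Cluster] = []
    cur: list = []
    cur_chrom, cur_end = None, None
    for chrom, s, e, cand in items:
        if cur and chrom == cur_chrom and s < cur_end:
            cur.append((s, e, cand))
            cur_end = max(cur_end, e)
        else:
            if len(cur) >= 2:
                clusters.append(_finish_cluster(cur_chrom, cur, window_max))
            cur = [(s, e, cand)]
            cur_chrom, cur_end = chrom, e
    if len(cur) >= 2:
        clusters.append(_finish_cluster(cur_chrom, cur, window_max))
    return clusters


def _finish_cluster(chrom, items, window_max) -> Cluster:
    start = min(s for s, _, _ in items)
    end = max(e for _, e, _ in items)
    if end - start > window_max:
        mid = (start + end) // 2
        start, end = mid - window_max // 2, mid + window_max // 2
    scores: dict[tuple[str, str], int] = {}
    for _, _, cand in items:
        for h in cand.alu_hits:
            key = (h.consensus, h.strand)
            scores[key] = scores.get(key, 0) + h.score
    (consensus, strand), _ = max(scores.items(), key=lambda kv: (kv[1], kv[0]))
    return Cluster(chrom, start, end, [c for _, _, c in items],
                   consensus, strand, [(s, e) for s, e, _ in items])


# ---------------------------------------------------------------------------
# The split DP
# ---------------------------------------------------------------------------

def split_map_read(seq: str, ref_window: str, consensus: str,
                   window_start: int = 0,
                   anchor_min: int = ANCHOR_MIN,
                   sc: Scoring = DEFAULT_SCORING,
                   read_name: str = "") -> SplitAlignment:
    """Best split alignment of one read over the window and one consensus.

    ``consensus`` must already be oriented (reverse-complemented for a minus
    strand hypothesis); reported consensus intervals are in that orientation.
    Junction ties resolve to the leftmost reference position.
    """
    if len(ref_window) > WINDOW_MAX:
        raise WindowTooLarge(
            f"reference window of {len(ref_window)} bp exceeds {WINDOW_MAX}; "
            "narrow the cluster")
    q = encode(seq)
    t = encode(ref_window)
    c = encode(consensus)
    n = len(q)
    A, Aarg = prefix_table(q, t, sc)
    B, Barg = suffix_table(q, t, sc)
    Ac, Acarg = prefix_table(q, c, sc)
    Bc, Bcarg = suffix_table(q, c, sc)

    ref_only = int(A.max())
    best = SplitAlignment(read_name, "ref", ref_only, ref_only)

    cons_only = int(Ac.max())
    if cons_only >= anchor_min and cons_only > best.score_split:
        best = SplitAlignment(read_name, "cons", cons_only, ref_only)

    # one jump: ref -> cons  (insertion-start junction)
    okA = A >= anchor_min
    okB = B >= anchor_min
    cand = np.where(okA & (Bc >= anchor_min), A + Bc, -1)
    i = int(cand.argmax())
    if cand[i] > best.score_split:
        jpos = window_start + int(Aarg[i])
        best = SplitAlignment(read_name, "ref_cons", int(cand[i]), ref_only,
                              [("start", jpos)])
    # one jump: cons -> ref  (insertion-end junction)
    cand = np.where((Ac >= anchor_min) & okB, Ac + B, -1)
    i = int(cand.argmax())
    if cand[i] > best.score_split:
        jpos = window_start + int(Barg[i])
        best = SplitAlignment(read_name, "cons_ref", int(cand[i]), ref_only,
                              [("end", jpos)])

    # two jumps: ref -> cons -> ref
    if n >= 3 * anchor_min:
        # cheap upper bound: perfect middle segment
        Amax = np.maximum.accumulate(np.where(okA, A, -10 ** 6) -
                                     sc.match * np.arange(n + 1))
        ub = int((Amax + np.where(okB, B, -10 ** 6) +
                  sc.match * np.arange(n + 1)).max())
        if ub > best.score_split:
            for i in range(anchor_min, n - 2 * anchor_min + 1):
                if not okA[i]:
                    continue
                mid, _ = global_query_rows(q[i:], c, sc)
                js = np.arange(i + anchor_min, n + 1 - anchor_min)
                if len(js) == 0:
                    continue
                vals = np.where(
                    (mid[js - i] >= anchor_min) & okB[js],
                    A[i] + mid[js - i] + B[js], -1)
                k = int(vals.argmax())
                if vals[k] > best.score_split:
                    j = int(js[k])
                    best = SplitAlignment(
                        read_name, "ref_cons_ref", int(vals[k]), ref_only,
                        [("start", window_start + int(Aarg[i])),
                         ("end", window_start + int(Barg[j]))])

    if best.has_alu:
        # consensus footprint of the read: end column of the best
        # end-anchored alignment, start column of the best start-anchored
        # one (identical to the full traceback when the optimum is unique)
        i0 = int(Ac.argmax())
        j0 = int(Bc.argmax())
        if Ac[i0] >= anchor_min:
            cs, ce = int(Bcarg[j0]), int(Acarg[i0])
            if cs < ce:
                best.cons_interval = (cs, ce)
    return best


def _oriented_consensus(library_seq: str, strand: str) -> str:
    return library_seq if strand == "+" else revcomp(library_seq)


def _to_plus_coords(interval, strand, cons_len):
    if interval is None:
        return None
    cs, ce = interval
    if strand == "+":
        return cs, ce
    return cons_len - ce, cons_len - cs


def summarize_cluster(cluster: Cluster, consensus_seq: str,
                      ref_window: str,
                      sc: Scoring = DEFAULT_SCORING) -> ClusterSummary:
    """Split-map every member read and aggregate per-cluster statistics.

    score_alu / score_null sum the best split and reference-only scores over
    *supporting* fragments (those whose best interpretation includes the
    insertion).  A breakpoint is detected when >= 1 supporting read reports
    a junction there; the modal junction position wins (ties leftmost).
    """
    oriented = _oriented_consensus(consensus_seq, cluster.strand)
    cons_len = len(consensus_seq)
    frag_results = []
    for cand in cluster.members:
        aligns = []
        for r in cand.template.reads:
            # a cleanly mapped read (no clip worth an anchor) cannot carry a
            # junction nor beat its own reference mapping: it contributes
            # equally to both hypotheses, so score it as a neutral
            # reference-only alignment without running the DP
            if r.is_mapped and r.max_clip < ANCHOR_MIN:
                aligns.append(SplitAlignment(r.name, "ref", 0, 0))
                continue
            seqs = [r.seq] if r.is_mapped else [r.seq, revcomp(r.seq)]
            best = None
            for s in seqs:
                a = split_map_read(s, ref_window, oriented,
                                   cluster.window_start, read_name=r.name)
                if best is None or a.score_split > best.score_split:
                    best = a
            aligns.append(best)
        frag_results.append((cand, aligns))

    supp = 0
    score_alu = score_null = 0.0
    start_votes: dict[int, int] = {}
    end_votes: dict[int, int] = {}
    inner: list[tuple[int, int]] = []
    for cand, aligns in frag_results:
        alu = sum(a.score_split for a in aligns)
        null = sum(a.score_ref_only for a in aligns)
        if alu > null and any(a.has_alu for a in aligns):
            supp += 1
            score_alu += alu
            score_null += null
            for a in aligns:
                for side, pos in a.junctions:
                    (start_votes if side == "start" else end_votes)[pos] = \
                        (start_votes if side == "start" else end_votes).get(pos, 0) + 1
                iv = _to_plus_coords(a.cons_interval, cluster.strand, cons_len)
                if iv is not None:
                    inner.append(iv)

    def _mode(votes):
        if not votes:
            return None, 0
        pos = max(votes, key=lambda p: (votes[p], -p))
        return pos, votes[pos]

    bp_start, reads_left = _mode(start_votes)
    bp_end, reads_right = _mode(end_votes)
    inner_min = min(s for s, _ in inner) + 1 if inner else 0   # 1-based
    inner_max = max(e for _, e in inner) if inner else 0
    return ClusterSummary(cluster, score_alu, score_null, supp,
                          inner_min, inner_max, bp_start, bp_end,
                          reads_left, reads_right)


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def build_confidence_interval(summary: ClusterSummary,
                              maxtsd: int = MAXTSD):
    """CI and TSD length from the detected breakpoints.

    Both detected: the CI is the TSD span [min(b_start,b_end),
    max(b_start,b_end)) and tsd_len = b_start - b_end (negative = target
    site loss).  One detected: the CI extends ``maxtsd`` bp on the
    undetected side so that the whole TSD of any usual insertion is
    contained.  Neither: intersection of the members' implied intervals
    (widest member interval when the intersection is empty).
    """
    bs, be = summary.bp_start, summary.bp_end
    if bs is not None and be is not None:
        return min(bs, be), max(bs, be), bs - be, frozenset({"start", "end"})
    if bs is not None:
        return bs - maxtsd, bs, None, frozenset({"start"})
    if be is not None:
        return be, be + maxtsd, None, frozenset({"end"})
    ivs = summary.cluster.implied
    lo = max(s for s, _ in ivs)
    hi = min(e for _, e in ivs)
    if lo >= hi:  # empty intersection: fall back to the widest member
        s, e = max(ivs, key=lambda iv: iv[1] - iv[0])
        return s, e, None, frozenset()
    return lo, hi, None, frozenset()


def call_from_summary(summary: ClusterSummary) -> AluCallRecord | None:
    if summary.supp < 2:
        return None
    ci_start, ci_end, tsd, bps = build_confidence_interval(summary)
    return AluCallRecord(
        chrom=summary.cluster.chrom,
        ci_start=ci_start, ci_end=ci_end,
        strand=summary.cluster.strand,
        reads_left=summary.reads_left, reads_right=summary.reads_right,
        tsd_len=tsd, breakpoints=bps,
        inner_min=summary.inner_min, inner_max=summary.inner_max,
        supp=summary.supp, score_alu=summary.score_alu,
        score_null=summary.score_null,
        family=summary.cluster.consensus)
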