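"""Comparisons across call sets: multi-set interval clustering, relative
precision/recall against external truth sets, Mendelian (trio) screening,
and coverage-window utilities.

Interval intersection is not transitive, so set comparisons use
single-linkage clustering over the union of calls (the same semantics as
``bedtools multiinter -cluster``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import AluCallRecord


def _ci_with_min_width(call: AluCallRecord, min_ci: int) -> tuple[int, int]:
    s, e = call.ci_start, call.ci_end
    if e - s < min_ci:
        pad = min_ci - (e - s)
        s -= pad // 2
        e += pad - pad // 2
    return s, e


@dataclass
class CallSetCluster:
    cluster_id: int
    chrom: str
    start: int
    end: int
    members: list[tuple[str, AluCallRecord]] = field(default_factory=list)

    @property
    def sources(self) -> frozenset:
        return frozenset(src for src, _ in self.members)


def cluster_call_sets(sets: dict[str, list[AluCallRecord]],
                      min_ci: int = 20) -> list[CallSetCluster]:
    """Single-linkage clusters over the union of several call sets.

    Every CI is first expanded to a minimum of ``min_ci`` bp to include a
    potential TSD.  Output order (and cluster ids) follow genomic position
    and are independent of input order.
    """
    items = []
    for src, calls in sets.items():
        for c in calls:
            s, e = _ci_with_min_width(c, min_ci)
            items.append((c.chrom, s, e, src, c))
    items.sort(key=lambda x: (x[0], x[1], x[2], x[3]))
    clusters: list[CallSetCluster] = []
    for chrom, s, e, src, c in items:
        cur = clusters[-1] if clusters else None
        if cur is not None and cur.chrom == chrom and s < cur.end:
            cur.members.append((src, c))
            cur.end = max(cur.end, e)
            cur.start = min(cur.start, s)
        else:
            clusters.append(CallSetCluster(len(clusters), chrom, s, e,
                                           [(src, c)]))
    return clusters


@dataclass(frozen=True)
class RelativeScore:
    prec_rel: float | None
    rec_rel: float | None


def _overlaps_any(call, sorted_truth, starts) -> bool:
    import bisect
    chrom_truth = sorted_truth.get(call.chrom)
    if not chrom_truth:
        return False
    st = starts[call.chrom]
    i = bisect.bisect_right(st, call.ci_end)
    for s, e in chrom_truth[:i][::-1]:
        if e < call.ci_start:
            if s < call.ci_start - 10_000:
                break
            continue
        if s <= call.ci_end and call.ci_start <= e:
            return True
    return False


def _index(calls):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append((c.ci_start, c.ci_end))
    starts = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort()
        starts[chrom] = [s for s, _ in by_chrom[chrom]]
    return by_chrom, starts


def relative_scores(calls, truth_union,
                    truth_same_individual=None) -> RelativeScore:
    """Relative precision and recall by CI overlap.

    prec_rel: fraction of calls matching the union of external call sets;
    rec_rel: fraction of the same-individual truth set matched (skipped if
    no such set is given).  Empty inputs give missing values.
    """
    t_ivs, t_starts = _index(truth_union)
    if calls:
        matched = sum(_overlaps_any(c, t_ivs, t_starts) for c in calls)
        prec = matched / len(calls)
    else:
        prec = None
    rec = None
    if truth_same_individual is not None:
        c_ivs, c_starts = _index(calls)
        if truth_same_individual:
            hit = sum(_overlaps_any(t, c_ivs, c_starts)
                      for t in truth_same_individual)
            rec = hit / len(truth_same_individual)
    return RelativeScore(prec, rec)


def mendelian_screen(child_filtered, father_unfiltered,
                     mother_unfiltered) -> list[AluCallRecord]:
    """Candidate de novo insertions: child calls with no CI overlap in the
    *unfiltered* (support >= 2) call set of either parent."""
    f_ivs, f_starts = _index(father_unfiltered)
    m_ivs, m_starts = _index(mother_unfiltered)
    return [c for c in child_filtered
            if not _overlaps_any(c, f_ivs, f_starts)
            and not _overlaps_any(c, m_ivs, m_starts)]


def coverage_windows(templates, chrom_lengths: dict[str, int],
                     window: int = 100, min_cov: float = 10.0,
                     extend: int = 50) -> dict[str, list[tuple[int, int]]]:
    """Regions where mean per-base coverage in 100 bp tiling windows
    reaches ``min_cov``; qualifying windows are merged, extended by
    ``extend`` bp and re-merged."""
    depth = {c: np.zeros(l + 1, dtype=np.int64)
             for c, l in chrom_lengths.items()}
    for t in templates:
        for r in t.reads:
            if r.is_mapped and r.chrom in depth:
                d = depth[r.chrom]
                d[r.pos] += 1
                d[min(r.end, len(d) - 1)] -= 1
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, d in depth.items():
        cov = np.cumsum(d[:-1])
        L = chrom_lengths[chrom]
        nwin = (L + window - 1) // window
        good = []
        for w in range(nwin):
            s, e = w * window, min((w + 1) * window, L)
            if cov[s:e].mean() >= min_cov:
                good.append((s, e))
        merged = _merge(good)
        extended = [(max(0, s - extend), min(L, e + extend))
                    for s, e in merged]
        out[chrom] = _merge(extended)
    return out


def _merge(ivs):
    res = []
    for s, e in sorted(ivs):
        if res and s <= res[-1][1]:
            res[-1] = (res[-1][0], max(res[-1][1], e))
        else:
            res.append((s, e))
    return res


def restrict_by_ci(calls, max_ci: int = 100):
    """WGS calls comparable to capture data: CI shorter than ``max_ci``
    (larger CIs are usually breakpoint-less and imprecisely placed)."""
    return [c for c in calls if c.ci_len < max_ci]
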