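"""Endonuclease nick-site preferences and insertion-placement models.

For every 6mer ``s`` the nick-site preference is

    p(s) = use(s) / (n * count(s))

where ``use(s)`` counts insertions whose nick context is ``s``, ``count(s)``
counts occurrences of ``s`` in the double-stranded genome, and ``n`` is the
number of insertions tallied.  p(s) is the probability that one new
insertion cleaves at one *specific* location carrying ``s``, so summing
p(6mer at x) over all positions x on both strands gives exactly 1.

Nick context convention (from the TT/AAAA notation, cut between T and A):
the 6mer spans 2 bases 5' and 4 bases 3' of the cut, read on the insertion
strand.  A plus-strand nick at between-base position x reads
``genome[x-2:x+4]``; a minus-strand nick reads the reverse complement of
``genome[x-4:x+2]``.  The nick is the element head junction: the insertion
start breakpoint for plus-strand calls and the insertion end breakpoint for
minus-strand calls.

Two placement models are compared: D_unif (every location equally likely)
and D_nick (uniform modulo the 6mer preferences).  Region enrichment or
depletion is assessed with a single-sided exact binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .align import encode, revcomp
from .models import AluCallRecord, ReferenceGenome, RepeatAnnotation, \
    RepeatRecord

log = logging.getLogger("aluscan")

K = 6
NK = 4 ** K
_POW = 4 ** np.arange(K - 1, -1, -1, dtype=np.int64)


def kmer_string(code: int) -> str:
    return "".join("ACGT"[(code >> (2 * (K - 1 - i))) & 3] for i in range(K))


def kmer_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = code * 4 + "ACGT".index(ch)
    return code


def kmer_codes_both_strands(seq: str):
    """Per-window 6mer codes on both strands.

    ``plus[i]`` encodes ``seq[i:i+6]`` and ``minus[i]`` its reverse
    complement; windows containing N are -1.
    """
    enc = encode(seq).astype(np.int64)
    L = len(seq)
    nwin = L - K + 1
    if nwin <= 0:
        return (np.empty(0, dtype=np.int64),) * 2
    plus = np.zeros(nwin, dtype=np.int64)
    valid = np.ones(nwin, dtype=bool)
    for l in range(K):
        b = enc[l:l + nwin]
        plus = plus * 4 + np.where(b == 4, 0, b)
        valid &= b != 4
    # revcomp code arithmetic: complement = 3 - base, order reversed
    minus = np.zeros(nwin, dtype=np.int64)
    for l in range(K):
        b = enc[l:l + nwin]
        minus = minus + np.where(b == 4, 0, 3 - b) * _POW[K - 1 - l]
    plus[~valid] = -1
    minus[~valid] = -1
    return plus, minus


def count_6mers(genome: ReferenceGenome) -> np.ndarray:
    """count(s) over the double-stranded genome (N windows skipped)."""
    counts = np.zeros(NK, dtype=np.int64)
    for rec in genome:
        plus, minus = kmer_codes_both_strands(rec.seq)
        for arr in (plus, minus):
            v = arr[arr >= 0]
            counts += np.bincount(v, minlength=NK)
    return counts


def nick_position(call: AluCallRecord):
    """Between-base nick site (head junction) of a call, or None.

    Requires the head-side breakpoint: insertion start for + calls,
    insertion end for - calls.
    """
    if call.strand == "+":
        return call.ci_end if "start" in call.breakpoints else None
    return call.ci_start if "end" in call.breakpoints else None


def nick_context(genome: ReferenceGenome, chrom: str, x: int,
                 strand: str) -> str | None:
    seq = genome.seq(chrom)
    if strand == "+":
        if x - 2 < 0 or x + 4 > len(seq):
            return None
        s = seq[x - 2:x + 4]
    else:
        if x - 4 < 0 or x + 2 > len(seq):
            return None
        s = revcomp(seq[x - 4:x + 2])
    return None if "N" in s else s


def nick_usage(calls, genome: ReferenceGenome) -> np.ndarray:
    """use(s): observed nick-context counts over a call set."""
    use = np.zeros(NK, dtype=np.int64)
    skipped = 0
    for c in calls:
        x = nick_position(c)
        if x is None:
            continue
        ctx = nick_context(genome, c.chrom, x, c.strand)
        if ctx is None:
            skipped += 1
            continue
        use[kmer_code(ctx)] += 1
    if skipped:
        log.warning("%d call(s) skipped: nick context unavailable near a "
                    "contig edge or N run", skipped)
    return use


@dataclass
class NickTable:
    use: np.ndarray
    count: np.ndarray
    n: int

    def __post_init__(self):
        bad = (self.use > 0) & (self.count == 0)
        if bad.any():
            raise ValueError(
                f"use > 0 with count = 0 for {kmer_string(int(np.nonzero(bad)[0][0]))}: "
                "usage inconsistent with the supplied genome")

    @property
    def p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(self.count > 0,
                         self.use / (self.n * np.maximum(self.count, 1)), 0.0)
        return p

    def p_of(self, kmer: str) -> float:
        return float(self.p[kmer_code(kmer)])

    def to_frame(self):
        import pandas as pd
        idx = np.nonzero(self.use)[0]
        order = idx[np.argsort(-self.p[idx], kind="stable")]
        return pd.DataFrame({
            "6mer": [kmer_string(int(c)) for c in order],
            "use": self.use[order],
            "count": self.count[order],
            "p_x1e10": self.p[order] * 1e10,
        })


def preference_table(use: np.ndarray, count: np.ndarray, n: int) -> NickTable:
    return NickTable(np.asarray(use), np.asarray(count), n)


def high_confidence_subset(call_sets) -> list[AluCallRecord]:
    """Stringent cross-individual subset for nick-site analysis.

    Keeps calls with both breakpoints detected, inner consensus span of at
    least 300 bp and a TSD shorter than 50 bp (and non-negative: target
    site losses are not TPRT products); overlapping calls between
    individuals are deduplicated keeping the first in (chrom, ci_start)
    order.
    """
    pool = []
    for calls in call_sets:
        for c in calls:
            if c.breakpoints != {"start", "end"}:
                continue
            if c.inner_len < 300:
                continue
            if c.tsd_len is None or not (0 <= c.tsd_len < 50):
                continue
            pool.append(c)
    pool.sort(key=lambda c: (c.chrom, c.ci_start, c.ci_end))
    kept: list[AluCallRecord] = []
    chain_end = None
    chain_chrom = None
    for c in pool:
        if kept and c.chrom == chain_chrom and c.ci_start < chain_end:
            chain_end = max(chain_end, c.ci_end)
            continue
        kept.append(c)
        chain_chrom, chain_end = c.chrom, c.ci_end
    return kept


# ---------------------------------------------------------------------------
# Insertion models
# ---------------------------------------------------------------------------

class InsertionModel:
    """D_unif or D_nick over a concrete genome.

    For D_nick, per-position probabilities are precomputed:
    ``pvec_plus[x] = p(genome[x-2:x+4])`` for the plus strand and the
    mirrored window for the minus strand; invalid windows (edges, N) carry
    zero mass.
    """

    def __init__(self, kind: str, genome: ReferenceGenome,
                 table: NickTable | None = None):
        if kind not in ("D_unif", "D_nick"):
            raise ValueError(kind)
        if kind == "D_nick" and table is None:
            raise ValueError("D_nick requires a NickTable")
        self.kind = kind
        self.genome = genome
        self.table = table
        self._plus: dict[str, np.ndarray] = {}
        self._minus: dict[str, np.ndarray] = {}
        if kind == "D_nick":
            p = table.p
            for rec in genome:
                L = len(rec.seq)
                plus_codes, minus_codes = kmer_codes_both_strands(rec.seq)
                vp = np.zeros(L + 1)
                vm = np.zeros(L + 1)
                idx = np.arange(len(plus_codes))
                okp = plus_codes >= 0
                okm = minus_codes >= 0
                vp[idx[okp] + 2] = p[plus_codes[okp]]
                vm[idx[okm] + 4] = p[minus_codes[okm]]
                self._plus[rec.name] = vp
                self._minus[rec.name] = vm
        self.total_positions = 2 * sum(len(r.seq) for r in genome)

    def segment_probability(self, chrom: str, start: int, end: int,
                            strands: str = "both") -> float:
        """Probability one insertion lands in [start, end) on the given
        strand(s).  Between-base positions x with start <= x < end belong to
        the segment, so probabilities over a partition of the genome add to
        the whole-genome value."""
        if start >= end:
            return 0.0
        L = self.genome.length(chrom)
        start, end = max(0, start), min(L, end)
        if self.kind == "D_unif":
            per_strand = (end - start) / self.total_positions
            return per_strand * (2 if strands == "both" else 1)
        tot = 0.0
        if strands in ("both", "+"):
            tot += float(self._plus[chrom][start:end].sum())
        if strands in ("both", "-"):
            tot += float(self._minus[chrom][start:end].sum())
        return tot

    def whole_genome_probability(self) -> float:
        return sum(self.segment_probability(r.name, 0, len(r.seq) + 1)
                   for r in self.genome)


def segment_probability(model: InsertionModel, segment, strands="both"):
    chrom, start, end = segment
    return model.segment_probability(chrom, start, end, strands)


# ---------------------------------------------------------------------------
# Clear Alus and their head/middle/tail regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClearAlu:
    """An isolated near-full-length reference Alu with clean end regions.

    head: 100 bp upstream of the element 5' end to 50 bp downstream of it;
    middle: between the end of head and the start of tail;
    tail: 50 bp upstream of the 3' end to 100 bp downstream; all in element
    orientation, stored as genome-coordinate intervals.
    """

    record: RepeatRecord
    head: tuple[int, int]
    middle: tuple[int, int]
    tail: tuple[int, int]

    @property
    def strand(self) -> str:
        return self.record.strand

    @property
    def chrom(self) -> str:
        return self.record.chrom


def clear_alus(annotation: RepeatAnnotation, min_sine_gap: int = 200,
               cons_start_max: int = 10, cons_end_range=(290, 350),
               max_len_diff: float = 0.10) -> list[ClearAlu]:
    """Reference Alus suitable for head/middle/tail proximity analysis:
    at least 200 bp from other SINEs, annotation starting before consensus
    position 10 and ending between 290 and 350, and genomic length within
    10% of the consensus span."""
    sines = sorted(annotation.sines(), key=lambda r: (r.chrom, r.start))
    out = []
    for i, rec in enumerate(sines):
        if not rec.repeat_name.startswith("Alu"):
            continue
        if not (1 <= rec.consensus_start < cons_start_max):
            continue
        if not (cons_end_range[0] <= rec.consensus_end <= cons_end_range[1]):
            continue
        span = rec.consensus_end - rec.consensus_start + 1
        if abs(rec.length - span) > max_len_diff * span:
            continue
        clear = True
        for j in (i - 1, i + 1):
            if 0 <= j < len(sines) and sines[j].chrom == rec.chrom:
                gap = max(sines[j].start - rec.end, rec.start - sines[j].end)
                if gap < min_sine_gap:
                    clear = False
        if not clear:
            continue
        s, e = rec.start, rec.end
        if rec.strand == "+":
            head = (s - 100, s + 50)
            tail = (e - 50, e + 100)
            middle = (s + 50, e - 50)
        else:
            head = (e - 50, e + 100)
            tail = (s - 100, s + 50)
            middle = (s + 50, e - 50)
        out.append(ClearAlu(rec, head, middle, tail))
    return out


def region_membership(call: AluCallRecord, region: tuple[int, int],
                      region_strand: str, orientation: str = "+") -> bool:
    """Is a call in a (stranded) region of a reference element?

    The call's TSD proxy (its CI) must intersect the region;
    ``orientation='+'`` asks for insertions in the same orientation as the
    element, ``'-'`` for the opposite, ``'any'`` ignores strand.
    """
    s, e = region
    if not call.overlaps(s, e):
        return False
    if orientation == "any":
        return True
    same = call.strand == region_strand
    return same if orientation == "+" else not same


def genic_region_sets(gene_annotation) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Region interval sets for genic enrichment rows.

    coding = merged CDS; noncoding_exon = exon minus CDS; introns =
    transcript span minus exons; genes = transcript spans; upstream_200 =
    the 200 bp 5' of each transcript start, strand-aware.  All merged,
    per chromosome, 0-based half-open.
    """
    cds = gene_annotation.merged("cds")
    exon = gene_annotation.merged("exon")
    span = gene_annotation.merged("span")

    def subtract(a, b):
        out = {}
        for chrom, ivs in a.items():
            cuts = b.get(chrom, [])
            res = []
            for s, e in ivs:
                cur = s
                for cs, ce in cuts:
                    if ce <= cur or cs >= e:
                        continue
                    if cs > cur:
                        res.append((cur, cs))
                    cur = max(cur, ce)
                if cur < e:
                    res.append((cur, e))
            out[chrom] = res
        return out

    upstream: dict[str, list[tuple[int, int]]] = {}
    for t in gene_annotation.transcripts:
        if not t.exons:
            continue
        if t.strand == "+":
            tss = t.exons[0][0]
            iv = (max(0, tss - 200), tss)
        else:
            tss = t.exons[-1][1]
            iv = (tss, tss + 200)
        upstream.setdefault(t.chrom, []).append(iv)
    from .io import _merge_intervals
    upstream = {c: _merge_intervals(v) for c, v in upstream.items()}
    return {
        "coding": cds,
        "noncoding_exon": subtract(exon, cds),
        "introns": subtract(span, exon),
        "genes": span,
        "upstream_200": upstream,
    }


def region_set_probability(model: InsertionModel, regions) -> float:
    """Model probability of a (merged, per-chromosome) region set, summed
    over both strands."""
    return sum(model.segment_probability(chrom, s, e)
               for chrom, ivs in regions.items() for s, e in ivs)


def count_calls_in_regions(calls, regions) -> int:
    """Calls whose CI intersects any interval of the region set."""
    n = 0
    for c in calls:
        ivs = regions.get(c.chrom, [])
        if any(c.ci_start <= e and s <= c.ci_end for s, e in ivs):
            n += 1
    return n


# ---------------------------------------------------------------------------
# Binomial enrichment test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    region: str
    obs: int
    n: int
    p_region: float
    expected: float
    p_value: float
    direction: str


def enrichment_test(obs: int, n: int, p_region: float,
                    correction_factor: float = 1.0,
                    region: str = "", two_sided: bool = False) -> EnrichmentResult:
    """Single-sided exact binomial test of observed vs expected insertions.

    ``correction_factor`` rescales the observation before testing (e.g.
    1.15 to compensate a 15% recall deficit near same-strand reference
    Alus); it is never applied implicitly.
    """
    if not (0.0 <= p_region <= 1.0):
        raise ValueError(f"p_region {p_region} outside [0, 1]")
    obs_c = int(round(obs * correction_factor))
    if not (0 <= obs_c <= n):
        raise ValueError("corrected observation outside [0, n]")
    expected = n * p_region
    if obs_c > expected:
        direction = "enriched"
        p = float(stats.binom.sf(obs_c - 1, n, p_region))
    else:
        direction = "depleted"
        p = float(stats.binom.cdf(obs_c, n, p_region))
    if two_sided:
        p = min(1.0, 2 * p)
    return EnrichmentResult(region, obs_c, n, p_region, expected, p, direction)
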