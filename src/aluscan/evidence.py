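"""Candidate-fragment discovery (pipeline steps i-iii).

From the initial mappings we keep fragments with insertion evidence:
partially mapped (clipped) reads, discordant insert sizes or orientations,
and pairs with one end unmapped.  Unmapped reads are progressively trimmed
and remapped; fragments are retained when at least one read maps with
MAPQ >= 5; surviving reads are screened against the Alu consensus library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import GenomeIndex, best_consensus_hit, revcomp
from .models import AluConsensusLibrary, ReadRecord, Template

log = logging.getLogger("aluscan")

#: soft/hard clip length that counts as a partial mapping
CLIP_MIN = 10
#: perfect-match score of the shortest mappable read; consensus-hit floor
EVIDENCE_SCORE_MIN = 20


@dataclass
class PairingProfile:
    """Per-read-group pairing information.

    ``frag_min``/``frag_max`` are the 0.05% and 99.95% template-length
    quantiles (0.1% outliers discarded in total, split evenly per tail).
    """

    read_group: str
    is_paired: bool
    frag_min: int = 0
    frag_max: int = 0
    read_len: int = 0

    def discordant(self, tlen: int) -> bool:
        return not (self.frag_min <= abs(tlen) <= self.frag_max)


@dataclass
class AluHit:
    read_name: str
    consensus: str
    cons_start: int   # 0-based half-open on the + consensus strand
    cons_end: int
    strand: str       # read orientation relative to the consensus
    score: int


@dataclass
class CandidateFragment:
    template: Template
    reasons: frozenset
    alu_hits: list[AluHit] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.template.name


def infer_pairing_profile(templates) -> dict[str, PairingProfile]:
    """Detect pairing and insert-size bounds per read group."""
    tlens: dict[str, list[int]] = {}
    paired: dict[str, bool] = {}
    rlens: dict[str, int] = {}
    any_mapped = False
    for t in templates:
        for r in t.reads:
            paired[t.read_group] = paired.get(t.read_group, False) or r.is_paired
            rlens[t.read_group] = max(rlens.get(t.read_group, 0), len(r.seq))
            any_mapped = any_mapped or r.is_mapped
        if len(t.reads) == 2:
            r1, r2 = t.reads
            if (r1.is_mapped and r2.is_mapped and r1.chrom == r2.chrom
                    and r1.strand != r2.strand and r1.tlen != 0):
                tlens.setdefault(t.read_group, []).append(abs(r1.tlen))
    if not any_mapped:
        raise ValueError("no mapped templates: cannot infer pairing profile")
    profiles = {}
    for rg, is_p in paired.items():
        if not is_p:
            profiles[rg] = PairingProfile(rg, False, read_len=rlens.get(rg, 0))
            continue
        lens = np.asarray(tlens.get(rg, []), dtype=float)
        if len(lens) == 0:
            raise ValueError(f"read group {rg}: paired but no mapped templates")
        if len(lens) < 1000:
            log.warning("read group %s: only %d proper templates for "
                        "quantile estimation", rg, len(lens))
        fmin = float(np.quantile(lens, 0.0005))
        fmax = float(np.quantile(lens, 0.9995))
        profiles[rg] = PairingProfile(rg, True, int(np.floor(fmin)),
                                      int(np.ceil(fmax)),
                                      read_len=rlens.get(rg, 0))
    return profiles


def extract_candidates(templates, profiles,
                       clip_min: int = CLIP_MIN) -> list[CandidateFragment]:
    """Emit templates with any insertion-evidence reason.

    Reasons: ``partial_mapping`` (soft/hard clip >= clip_min),
    ``discordant_insert`` (template length outside the profile bounds, wrong
    orientation, or mates on different chromosomes) and ``one_end_unmapped``.
    """
    out = []
    for t in templates:
        profile = profiles.get(t.read_group)
        reasons = set()
        mapped = [r for r in t.reads if r.is_mapped]
        if any(r.is_mapped and r.max_clip >= clip_min for r in t.reads):
            reasons.add("partial_mapping")
        if profile is not None and profile.is_paired and len(t.reads) == 2:
            if len(mapped) == 1:
                reasons.add("one_end_unmapped")
            elif len(mapped) == 2:
                r1, r2 = mapped
                if r1.chrom != r2.chrom or r1.strand == r2.strand:
                    reasons.add("discordant_insert")
                else:
                    left, right = (r1, r2) if r1.pos <= r2.pos else (r2, r1)
                    if left.strand != "+" or right.strand != "-":
                        reasons.add("discordant_insert")
                    elif profile.discordant(max(r1.end, r2.end) -
                                            min(r1.pos, r2.pos)):
                        reasons.add("discordant_insert")
        if reasons:
            out.append(CandidateFragment(t, frozenset(reasons)))
    return out


@dataclass
class RemappedRead:
    read: ReadRecord
    trim_5: int
    trim_3: int
    mapping: dict | None   # GenomeIndex.map_read result or None

    @property
    def is_mapped(self) -> bool:
        return self.mapping is not None


def progressive_remap(read: ReadRecord, index: GenomeIndex,
                      min_len: int = 20,
                      increment: int = 5) -> RemappedRead:
    """Map a read, trimming 5' then 3' in fixed increments until it maps.

    First the full read is tried; then 5' trims down to ``min_len`` retained
    bases; then the read is restored and trimmed from the 3' end.  The first
    successful mapping wins.
    """
    seq = read.seq
    n = len(seq)
    if n < min_len:
        return RemappedRead(read, 0, 0, None)
    hit = index.map_read(seq)
    if hit:
        return RemappedRead(read, 0, 0, hit)
    for trim in range(increment, n - min_len + 1, increment):
        hit = index.map_read(seq[trim:])
        if hit:
            return RemappedRead(read, trim, 0, hit)
    for trim in range(increment, n - min_len + 1, increment):
        hit = index.map_read(seq[:n - trim])
        if hit:
            return RemappedRead(read, 0, trim, hit)
    return RemappedRead(read, 0, 0, None)


def retain_by_mapq(candidates, threshold: int = 5):
    """Keep fragments with at least one read mapped at MAPQ >= threshold."""
    return [c for c in candidates if any(
        r.is_mapped and r.mapq >= threshold for r in c.template.reads)]


class _KmerPrescreen:
    """Cheap shared-k-mer screen against the consensus library."""

    def __init__(self, library: AluConsensusLibrary, k: int = 14):
        self.k = k
        self.kmers: set[str] = set()
        for rec in library:
            for s in (rec.seq, revcomp(rec.seq)):
                for i in range(0, len(s) - k + 1):
                    self.kmers.add(s[i:i + k])

    def maybe_hits(self, seq: str) -> bool:
        k = self.k
        if len(seq) < k:
            return False
        return any(seq[i:i + k] in self.kmers
                   for i in range(0, len(seq) - k + 1, 4))


def find_alu_evidence(candidates, library: AluConsensusLibrary,
                      score_min: int = EVIDENCE_SCORE_MIN,
                      prescreen: bool = True) -> list[CandidateFragment]:
    """Attach the best consensus hit per read; keep fragments with >= 1 hit.

    Each read is aligned locally against every library entry on both
    strands; the single best hit at or above ``score_min`` (the score of a
    perfect 20 bp match) is retained per read.
    """
    if len(library) == 0:
        raise ValueError("empty consensus library")
    screen = _KmerPrescreen(library) if prescreen else None
    out = []
    for cand in candidates:
        hits = []
        for r in cand.template.reads:
            if screen is not None and not screen.maybe_hits(r.seq):
                continue
            best = None
            for rec in library:
                score, strand, cs, ce = best_consensus_hit(r.seq, rec.seq)
                if score >= score_min and (best is None or score > best.score):
                    best = AluHit(r.name, rec.name, cs, ce, strand, score)
            if best is not None:
                hits.append(best)
        if hits:
            cand.alu_hits = hits
            out.append(cand)
    return out
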