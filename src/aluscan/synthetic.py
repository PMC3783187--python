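"""Seeded generators: reference genomes with planted Alus, TPRT insertions,
and paired reads with truth-guided alignments.

The generator reproduces the TPRT end product: an endonuclease nick at a
between-base position ``x`` (drawn uniformly or per a 6mer preference
table), a target-site duplication of 4-25 bp, the (possibly 5'-truncated)
consensus plus a poly-A tail, and a ~50/50 strand choice.  On the plus
strand the left TSD copy's right end sits at the nick; the minus strand is
the exact reverse-complement mirror.

Reads are aligned by a truth-guided mapper (coordinates are known by
construction), so the pipeline is testable without an external aligner.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .align import revcomp
from .models import (
    AluConsensusLibrary,
    ReadRecord,
    ReferenceGenome,
    RepeatAnnotation,
    RepeatRecord,
    SequenceRecord,
    Template,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def make_consensus_library(seed: int = 7, polya: int = 30) -> AluConsensusLibrary:
    """Synthetic stand-ins for Alu consensus sequences.

    Two entries: a young 'AluY_syn' (281 bp body + poly-A, 311 bp total,
    long enough to satisfy the >=310 bp excisable-element floor) and an older
    'AluSx_syn'.  Purely synthetic fixtures; real analyses should supply a
    Dfam/RepBase consensus FASTA instead.
    """
    rng = np.random.default_rng(seed)
    body_y = _random_dna(rng, 281)
    body_s = _random_dna(rng, 270)
    return AluConsensusLibrary([
        SequenceRecord("AluY_syn", body_y + "A" * polya),
        SequenceRecord("AluSx_syn", body_s + "A" * polya),
    ])


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def make_reference(seed: int, length: int, n_fixed_alus: int,
                   divergence: float = 0.10, frac_excisable: float = 0.5,
                   chrom: str = "chr1",
                   library: AluConsensusLibrary | None = None,
                   min_tsd: int = 6, max_tsd: int = 16):
    """Random genome with planted fixed Alus.

    A ``frac_excisable`` share are planted as young AluYs: near-identical to
    consensus (1% divergence) and flanked by a perfect TSD of
    ``min_tsd``..``max_tsd`` bp, i.e. they satisfy the excisability criteria
    used by the faux-reference simulation.  The rest are older AluS copies
    mutated at ``divergence`` with no clean TSD.

    Returns ``(ReferenceGenome, RepeatAnnotation, AluConsensusLibrary)``.
    """
    if n_fixed_alus and length < 10 * (n_fixed_alus * 350):
        raise ValueError("overcrowded genome: need length >= 10*(n_alus*350)")
    rng = np.random.default_rng(seed)
    library = library or make_consensus_library()
    background = _random_dna(rng, length)
    if n_fixed_alus == 0:
        return (ReferenceGenome([SequenceRecord(chrom, background)]),
                RepeatAnnotation([]), library)

    n_exc = int(round(n_fixed_alus * frac_excisable))
    # well-separated anchors: draw in a gap-reduced range, then re-inflate
    margin, min_sep = 1000, 1200
    usable = length - 2 * margin - (n_fixed_alus - 1) * min_sep
    if usable <= n_fixed_alus:
        raise ValueError("overcrowded genome: cannot separate planted Alus")
    anchors = np.sort(rng.choice(np.arange(usable), size=n_fixed_alus,
                                 replace=False))
    anchors = anchors + margin + np.arange(n_fixed_alus) * min_sep

    pieces, records = [], []
    prev = 0
    offset = 0  # accumulated inserted length
    for i, a in enumerate(anchors):
        a = int(a)
        excisable = i < n_exc
        name = "AluY_syn" if excisable else "AluSx_syn"
        strand = "+" if rng.random() < 0.5 else "-"
        cons = library.seq(name)
        elem = _mutate(rng, cons, 0.01 if excisable else divergence)
        if strand == "-":
            elem_g = revcomp(elem)
        else:
            elem_g = elem
        pieces.append(background[prev:a])
        if excisable:
            tsd = _random_dna(rng, int(rng.integers(min_tsd, max_tsd + 1)))
            insert = tsd + elem_g + tsd
            alu_start = a + offset + len(tsd)
        else:
            insert = elem_g
            alu_start = a + offset
        pieces.append(insert)
        records.append(RepeatRecord(
            chrom, alu_start, alu_start + len(elem_g), strand, name,
            "SINE/Alu", 1, len(cons)))
        offset += len(insert)
        prev = a
    pieces.append(background[prev:])
    genome = "".join(pieces)
    return (ReferenceGenome([SequenceRecord(chrom, genome)]),
            RepeatAnnotation(records), library)


# ---------------------------------------------------------------------------
# TPRT insertions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionSpec:
    """Truth record for one planted insertion (reference coordinates).

    ``nick`` is the endonuclease nick site (= head junction); ``b_start`` /
    ``b_end`` are the insertion start/end breakpoints with
    ``b_start - b_end = tsd_len``; the inserted block occupies
    ``[donor_start, donor_end)`` in the donor.
    """

    chrom: str
    nick: int
    strand: str
    consensus: str
    truncation: int
    polya_len: int
    tsd_len: int
    b_start: int
    b_end: int
    donor_start: int
    donor_end: int


@dataclass
class SyntheticWorld:
    reference: ReferenceGenome
    chrom: str
    donor_seq: str
    insertions: list[InsertionSpec]
    blocks: list[tuple[int, int, int]]  # (donor_start, donor_end, ref_start)
    library: AluConsensusLibrary
    seed: int
    annotation: RepeatAnnotation = field(default_factory=lambda: RepeatAnnotation([]))


def _draw_nicks(rng, genome: str, n: int, model, margin: int, min_sep: int):
    """Draw (nick, strand) pairs. model: 'uniform' or {6mer: weight}."""
    L = len(genome)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    if model == "uniform":
        def draw(strand):
            return int(rng.integers(margin, L - margin))
    else:
        from .nicksites import kmer_codes_both_strands
        plus_codes, minus_codes = kmer_codes_both_strands(genome)
        lut = np.zeros(4 ** 6, dtype=float)
        for kmer, w in model.items():
            code = 0
            for ch in kmer:
                code = code * 4 + "ACGT".index(ch)
            lut[code] = w
        # nick x on + strand reads genome[x-2:x+4] (window start x-2);
        # on - strand reads rc(genome[x-4:x+2]) (window start x-4).
        w_plus = np.zeros(L + 1)
        w_minus = np.zeros(L + 1)
        valid_p = plus_codes >= 0
        valid_m = minus_codes >= 0
        idx = np.arange(len(plus_codes))
        w_plus[idx[valid_p] + 2] = lut[plus_codes[valid_p]]
        w_minus[idx[valid_m] + 4] = lut[minus_codes[valid_m]]
        w_plus[:margin] = w_plus[L - margin:] = 0
        w_minus[:margin] = w_minus[L - margin:] = 0
        if w_plus.sum() == 0 or w_minus.sum() == 0:
            raise ValueError("preference model assigns no mass in range")
        pp = w_plus / w_plus.sum()
        pm = w_minus / w_minus.sum()
        positions = np.arange(L + 1)

        def draw(strand):
            p = pp if strand == "+" else pm
            return int(rng.choice(positions, p=p))
    chosen: list[tuple[int, str]] = []
    for s in map(str, strands):
        for _ in range(1000):
            x = draw(s)
            if all(abs(x - c) >= min_sep for c, _ in chosen):
                chosen.append((x, s))
                break
        else:
            raise ValueError("could not place insertions with 500 bp isolation")
    return sorted(chosen)


def _junction_microhomology(genome: str, b_start: int, b_end: int,
                            ins_seq: str, prec: str | None,
                            foll: str | None) -> bool:
    """True when a junction base tie makes a breakpoint unidentifiable.

    ``prec``/``foll`` are the oriented-consensus bases immediately before /
    after the inserted block (None at a consensus end).  A tie lets an
    equal-scoring split alignment shift the junction by >= 1 bp.
    """
    if genome[b_start] == ins_seq[0]:
        return True
    if prec is not None and genome[b_start - 1] == prec:
        return True
    if genome[b_end - 1] == ins_seq[-1]:
        return True
    if foll is not None and genome[b_end] == foll:
        return True
    return False


def plant_insertions(reference: ReferenceGenome,
                     library: AluConsensusLibrary,
                     n: int, model, seed: int,
                     tsd_dist=None, polya_dist=None, trunc_dist=None,
                     consensus_name: str | None = None,
                     min_sep: int = 500,
                     avoid_microhomology: bool = False,
                     nicks=None) -> SyntheticWorld:
    """Plant ``n`` TPRT insertions in the (single-chromosome) reference.

    ``model`` is ``"uniform"`` or a ``{6mer: weight}`` preference table.
    Default distributions: TSD ~ U{8..16}, poly-A ~ U{10..30}, no truncation
    with probability 0.8 else U{1..150}.  With ``avoid_microhomology`` nick
    sites whose junction context ties with the element ends are redrawn, so
    every planted breakpoint is uniquely identifiable (used by exactness
    tests; real TPRT has no such constraint).  An explicit ``nicks`` list of
    (position, strand) pairs overrides the model draw entirely.
    """
    rng = np.random.default_rng(seed)
    rec = reference.records[0]
    genome, chrom = rec.seq, rec.name
    tsd_dist = tsd_dist or (lambda r: int(r.integers(8, 17)))
    polya_dist = polya_dist or (lambda r: int(r.integers(10, 31)))
    trunc_dist = trunc_dist or (
        lambda r: 0 if r.random() < 0.8 else int(r.integers(1, 151)))
    consensus_name = consensus_name or library.names[0]

    if nicks is None:
        nicks = _draw_nicks(rng, genome, n, model, margin=300,
                            min_sep=min_sep)
    else:
        nicks = sorted((int(x), str(s)) for x, s in nicks)

    body = library.seq(consensus_name).rstrip("A")  # library poly-A removed
    specs = []
    xs = [x for x, _ in nicks]
    for idx, (x, strand) in enumerate(nicks):
        t = tsd_dist(rng)
        trunc = trunc_dist(rng)
        polya = polya_dist(rng)
        elem = body[trunc:] + "A" * polya
        if strand == "+":
            ins_seq = elem                        # nick at head junction
            prec = body[trunc - 1] if trunc > 0 else None
            foll = "A"                            # A-rich consensus tail
        else:
            ins_seq = revcomp(elem)
            prec = "T"                            # complement of tail A
            foll = revcomp(body[trunc - 1]) if trunc > 0 else None

        def _bounds(xx):
            pos = xx if strand == "+" else xx + t
            return pos, pos - t
        pos_ins, b_end = _bounds(x)
        if avoid_microhomology:
            tries = 0
            while _junction_microhomology(genome, pos_ins, b_end, ins_seq,
                                          prec, foll):
                tries += 1
                if tries > 5000:
                    raise ValueError("cannot avoid junction microhomology")
                x2 = int(rng.integers(300, len(genome) - 300))
                if any(abs(x2 - o) < min_sep
                       for j, o in enumerate(xs) if j != idx):
                    continue
                x = x2
                xs[idx] = x
                pos_ins, b_end = _bounds(x)
        specs.append((pos_ins, x, strand, t, trunc, polya, ins_seq))
    specs.sort(key=lambda s: s[0])

    donor_parts: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    insertions: list[InsertionSpec] = []
    prev = 0       # reference cursor
    dpos = 0       # donor cursor
    for pos_ins, x, strand, t, trunc, polya, ins_seq in specs:
        donor_parts.append(genome[prev:pos_ins])
        blocks.append((dpos, dpos + pos_ins - prev, prev))
        dpos += pos_ins - prev
        donor_parts.append(ins_seq)
        insertions.append(InsertionSpec(
            chrom, x, strand, consensus_name, trunc, polya, t,
            pos_ins, pos_ins - t, dpos, dpos + len(ins_seq)))
        dpos += len(ins_seq)
        prev = pos_ins - t  # duplicate the TSD
    donor_parts.append(genome[prev:])
    blocks.append((dpos, dpos + len(genome) - prev, prev))
    donor = "".join(donor_parts)
    return SyntheticWorld(reference, chrom, donor, insertions, blocks,
                          library, seed)


def excise_insertions(world: SyntheticWorld) -> str:
    """Reverse surgery: remove every inserted block plus one TSD copy.

    Returns a sequence that must equal the reference byte-for-byte.
    """
    donor = world.donor_seq
    out = []
    prev = 0
    for ins in world.insertions:
        # remove the inserted block and the upstream duplicate of the TSD
        out.append(donor[prev:ins.donor_start - ins.tsd_len])
        prev = ins.donor_end
    out.append(donor[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Read simulation with truth-guided alignment
# ---------------------------------------------------------------------------

def simulate_reads(world: SyntheticWorld, read_len: int = 100,
                   frag_mean: float = 300.0, frag_sd: float = 30.0,
                   coverage: float = 20.0, error_rate: float = 0.0,
                   seed: int = 0, read_group: str = "sim",
                   min_anchor: int = 20) -> list[Template]:
    """Paired FR reads from the donor, aligned against the reference.

    Fragment count = coverage * donor_len / (2 * read_len).  Alignments are
    produced by intersecting each read's donor interval with the known
    donor<->reference shared blocks: the longest shared piece becomes the
    aligned segment (soft-clipping the rest); reads with no shared piece of
    at least ``min_anchor`` bp are emitted unmapped.  Substitution errors
    only, so CIGARs stay clip/match/clip.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if frag_mean <= read_len:
        raise ValueError("frag_mean must exceed read_len")
    rng = np.random.default_rng(seed)
    donor = world.donor_seq
    L = len(donor)
    n_frag = int(round(coverage * L / (2 * read_len)))
    starts = rng.integers(0, L - read_len, size=n_frag)
    lengths = np.maximum(
        read_len, np.rint(rng.normal(frag_mean, frag_sd, size=n_frag)).astype(int))
    lengths = np.minimum(lengths, L - starts)
    flip = rng.random(n_frag) < 0.5

    block_starts = [b[0] for b in world.blocks]

    def align(a: int, b: int):
        """Longest shared sub-interval of donor [a,b); None if < min_anchor."""
        i = bisect.bisect_right(block_starts, a) - 1
        best = None
        while i < len(world.blocks) and world.blocks[i][0] < b:
            ds, de, rs = world.blocks[i]
            lo, hi = max(a, ds), min(b, de)
            if hi - lo > 0 and (best is None or hi - lo > best[1] - best[0]):
                best = (lo, hi, rs + (lo - ds))
            i += 1
        if best is None or best[1] - best[0] < min_anchor:
            return None
        return best

    templates = []
    chrom = world.chrom
    err_count = 0
    for k in range(n_frag):
        s = int(starts[k])
        e = s + int(lengths[k])
        iv1 = (s, min(s + read_len, e))
        iv2 = (max(e - read_len, s), e)
        name = f"frag{k:07d}"
        reads = []
        specs = [(iv1, "+", True), (iv2, "-", False)]
        if flip[k]:
            specs = [(iv1, "+", False), (iv2, "-", True)]
        for (a, b), strand, is_r1 in specs:
            seq = donor[a:b]
            if error_rate > 0:
                seq = _mutate(rng, seq, error_rate)
                err_count += 1
            hit = align(a, b)
            if hit is None:
                reads.append(ReadRecord(
                    name=name, seq=seq, read_group=read_group,
                    is_mapped=False, strand=strand, is_paired=True,
                    is_read1=is_r1, mapq=0))
            else:
                lo, hi, rpos = hit
                reads.append(ReadRecord(
                    name=name, seq=seq, read_group=read_group,
                    is_mapped=True, chrom=chrom, pos=rpos, strand=strand,
                    clip_left=lo - a, clip_right=b - hi,
                    aligned_len=hi - lo, mapq=60, is_paired=True,
                    is_read1=is_r1))
        r1, r2 = reads
        for r, m in ((r1, r2), (r2, r1)):
            r.mate_mapped = m.is_mapped
            if m.is_mapped:
                r.mate_chrom, r.mate_pos, r.mate_strand = m.chrom, m.pos, m.strand
        if r1.is_mapped and r2.is_mapped and r1.chrom == r2.chrom:
            span = max(r1.end, r2.end) - min(r1.pos, r2.pos)
            r1.tlen = span if r1.pos <= r2.pos else -span
            r2.tlen = -r1.tlen
        t = Template(name, read_group, reads)
        templates.append(t)
    return templates


# ---------------------------------------------------------------------------
# Faux-reference bundles
# ---------------------------------------------------------------------------

SCALES = {
    "tiny": dict(length=200_000, n_alus=20, coverage=20.0),
    "desk": dict(length=2_000_000, n_alus=200, coverage=20.0),
}


def faux_world(seed: int, scale: str = "tiny", error_rate: float = 0.0):
    """Deterministic faux-reference bundle for benchmarking the caller.

    Builds a reference with planted excisable AluYs (tiny: 200 kb with 10,
    desk: 2 Mb with 100, plus as many non-excisable AluS decoys), excises
    the qualifying elements to obtain the faux reference, and simulates
    paired 100 bp reads (insert 300 +/- 30, 20x) from the *intact* genome,
    truth-aligned against the faux reference.

    Returns ``(fw, templates, reference, annotation, library)`` where ``fw``
    is the :class:`~aluscan.fauxsim.FauxWorld` carrying the truth TSD
    intervals.
    """
    from .fauxsim import build_faux_reference, select_excisable

    if scale not in SCALES:
        raise ValueError(f"scale must be one of {sorted(SCALES)}")
    p = SCALES[scale]
    rng = np.random.default_rng(seed)
    s_ref, s_reads = int(rng.integers(0, 2 ** 31)), int(rng.integers(0, 2 ** 31))
    reference, annotation, library = make_reference(
        s_ref, p["length"], p["n_alus"], frac_excisable=0.5)
    excisable = select_excisable(reference, annotation)
    fw = build_faux_reference(reference, excisable)
    # the intact genome acts as the donor carrying one "insertion" per excision
    world = SyntheticWorld(
        reference=fw.faux, chrom=world_chrom(reference),
        donor_seq=reference.records[0].seq,
        insertions=[], blocks=fw.donor_blocks, library=library, seed=seed,
        annotation=annotation)
    templates = simulate_reads(
        world, read_len=100, frag_mean=300.0, frag_sd=30.0,
        coverage=p["coverage"], error_rate=error_rate, seed=s_reads)
    return fw, templates, reference, annotation, library


def world_chrom(reference: ReferenceGenome) -> str:
    return reference.records[0].name
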