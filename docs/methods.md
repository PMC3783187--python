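# Methods

## The detection model

`aluscan` calls novel Alu retrotransposon insertions from paired short-read
mappings by combining read-pair and split-read evidence. Alu elements
(~300 bp SINEs; families AluJ/AluS/AluY, with only some AluY subfamilies
still retrotransposition-competent) insert by target-primed reverse
transcription (TPRT): the L1 endonuclease nicks one strand, reverse
transcriptase copies the Alu RNA in place, and repair of the staggered
breaks duplicates 4–25 bp of the target site on both sides of the new
element (the TSD). In a donor genome an insertion therefore reads
`…L [TSD] [Alu + poly-A] [TSD] R…` where the reference reads
`…L [TSD] R…`. Reads from the donor that cross a junction map to the
reference with soft-clipped tails; read pairs that straddle the element map
with discordant inserts or one unmapped mate.

The pipeline:

1. **Pairing profile.** Per read group, template-length bounds are the
   0.05% and 99.95% empirical quantiles of proper-pair insert sizes (0.1%
   outliers discarded in total, split evenly per tail; the original
   description does not say one- or two-sided, we chose symmetric).
2. **Candidate fragments.** A template is a candidate if any read carries a
   soft/hard clip ≥ 10 bp (`partial_mapping`), the insert size or
   orientation is discordant, or exactly one mate is unmapped. The 10 bp
   clip floor is our choice, balancing sensitivity against adapter noise.
3. **Progressive remap.** Unmapped reads can be trimmed from the 5′ end in
   5 bp increments (1 bp where tests need exactness) down to 20 bp until
   they map, then from the 3′ end. With input mappings that already contain
   soft-clipped alignments (any modern aligner, and the truth-guided
   simulator) this step rescues nothing, so the pipeline leaves it off by
   default; it remains available for mappings produced by end-to-end-only
   aligners. Templates are kept only if some read maps with MAPQ ≥ 5.
4. **Consensus evidence.** Candidate reads are locally aligned to every
   consensus entry on both strands; the best hit at or above the score of a
   perfect 20 bp match counts as Alu evidence (a cheap shared-14-mer screen
   skips hopeless reads first).
5. **Clustering.** Each fragment implies an insertion-locus interval
   (clip-anchored: junction ± 25 bp; otherwise anchor end to anchor start +
   frag_max on the anchor's 3′ side). Implied intervals merge by single
   linkage; clusters need ≥ 2 fragments. One consensus entry and strand are
   fixed per cluster (highest summed hit score) for determinism.
6. **Split mapping.** Every member read is aligned allowing jumps between
   the cluster's reference window and the oriented consensus (see below).
   A cluster summary accumulates, over *supporting* fragments (best
   interpretation includes the insertion), the split and reference-only
   score sums, the consensus positions covered (`inner_min..inner_max`),
   and junction votes; the modal junction per side (ties to the leftmost
   reference position) becomes a detected breakpoint with its spanning-read
   counts.
7. **Confidence intervals.** Junctions are between-base reference
   positions. The jump out of the reference detects the insertion start
   `b_start` (right end of the TSD); the jump back detects the insertion
   end `b_end` (left end of the TSD). Both detected: CI = the TSD span,
   `tsd_len = b_start − b_end` (negative = target site loss; 0 = blunt).
   One detected: the CI extends MAXTSD = 25 bp on the undetected side, so
   usual TSDs are always contained and independent one-sided detections of
   the same insertion overlap. Neither: intersection of the members'
   implied intervals (widest member interval if empty). Exports are 1-based
   inclusive; everything internal is 0-based half-open.

### The split-alignment objective

Scoring follows the internal aligner contract: match +1, mismatch −2, gap
open −4, gap extend −1 (a k-gap costs 4 + (k−1)). The configurations are
reference-only, one jump (ref→cons or cons→ref), two jumps
(ref→cons→ref), and consensus-only. Jump points partition the read: outer
pieces are soft-clipped at their outer end and anchored at the jump; the
two-jump middle piece consumes every read base between its jumps
(consensus-local). Each piece must score ≥ `anchor_min` = 8 — with unit
match score this forces ≥ 8 net matched bases per segment and suppresses
spurious 1-base jumps. The DP is an exact vectorised Gotoh with per-row
prefix/suffix score tables; a cheap upper bound gates the quadratic
two-jump search, which only fires for reads that can span a whole (short)
insertion. Junction ties resolve to the leftmost reference position; an
equal-scoring tie is real ambiguity (junction microhomology), so reported
breakpoints can shift by the homology length. The synthetic generator has
an `avoid_microhomology` mode that redraws nick sites whose junction
context ties with the element ends; exactness tests use it, benchmark
worlds do not.

The reference window per cluster is capped at 5 000 bp to bound the DP.
MAPQ from the internal seed-and-extend mapper is the best-minus-second-best
locus score clamped to [0, 60].

## Filtering

Four thresholds: `len` (inner consensus span, `inner_max − inner_min + 1`),
`supp` (supporting fragments; the unfiltered floor is 2), `null` (relative
score improvement `(score_alu − score_null)/score_alu`, in percent — the
source material calls this a "difference" and grids it 0–30%, which
implies a relative measure; an absolute mode is a one-line change), and
`ci-len`. Calls whose CI (extended by 25 bp) lies near a same-strand
reference Alu additionally need one *non-ambiguous* detected breakpoint:
the call's head-side breakpoint is ambiguous when the reference Alu's head
falls in the window (diverged reference copies can siphon reads to the
consensus), likewise tail with tail. The proximity window (CI ± MAXTSD) is
our quantification of "close to". The exome preset fixes `supp ≥ 10` (the
one clearly stated capture-data threshold) with package defaults for the
rest (150 / 10% / 700), flagged as such in the CLI help.

## Faux-reference calibration

Filter thresholds are data-set-specific, so they are selected by
simulation that avoids both classic biases (unrealistic planted insertions,
unrealistic simulated reads): reference AluYs ≥ 310 bp flanked by a
perfect TSD of 6–25 bp — elements that look like recent TPRT products —
are excised together with their *downstream* TSD copy (one copy must go;
downstream keeps truth intervals upstream-anchored). Real (or, here,
simulated-from-the-intact-genome) reads are then detected against this
faux reference. A call is a true positive iff its CI intersects the
remaining TSD; simulated precision is TP/P over calls and simulated recall
counts distinct excisions recovered over T. A 10,500-setting grid
(len 150–290 step 10; supp 6–25; null 0–30% step 5; ci-len 300–1100 step
200) is scored in memory on one unfiltered run — re-detection per setting
would give identical results at 10,500× the cost — and the selected
setting maximises recall subject to precision ≥ x (default x = 0.97; ties
break by precision, then stricter support, then ascending setting order).
Known-polymorphism call sets, when supplied, are mapped through the
coordinate map and excluded before scoring; the default is the empty set
since external catalogues are not bundled.

## Nick-site preferences and insertion models

For the nick analysis only stringent calls are used: both breakpoints
detected, inner span ≥ 300 bp, and TSD length in [0, 50) bp (< 50
consistent with TPRT; we additionally exclude negative target-site losses,
which TPRT does not produce), deduplicated across individuals by
single-linkage overlap keeping the first in coordinate order.

The nick 6mer spans 2 bases 5′ and 4 bases 3′ of the cut, read on the
insertion strand — the frame implied by the TT/AAAA notation (cut between
T and A). The nick is the element *head* junction, where the original
cleavage context survives the insertion: `b_start` for + calls (context
`genome[x−2:x+4]`), `b_end` for − calls (reverse complement of
`genome[x−4:x+2]`); the two frames are exact mirror images under genome
reverse complement. The preference is

    p(s) = use(s) / (n · count(s)),

with `count(s)` over both strands of the genome (N windows skipped) and
`n` the number of insertions tallied, so p(s) is the probability that one
insertion cuts at one specific site carrying s, and
Σ_s count(s)·p(s) = Σ_s use(s)/n = 1 for a complete tally.

Two placement models: `D_unif` (uniform over between-base positions,
both strands) and `D_nick` (position x on a strand gets p(6mer at x)).
Segment probabilities enumerate positions half-open, so any partition of
the genome sums exactly to the whole-genome mass (1 for a self-consistent
table). Region tests use the single-sided exact binomial
(direction chosen by observed vs expected; a two-sided variant sits behind
a flag), with an optional explicit recall-correction factor (e.g. 1.15
where detection near same-strand reference Alus runs ~15% behind
genome-wide recall) that multiplies the observation, rounded to the
nearest integer — it is never applied silently.

"Clear" reference Alus for head/middle/tail analyses: ≥ 200 bp from other
SINEs, annotation starting before consensus position 10 and ending in
290–350, genomic length within 10% of the consensus span. Regions in
element orientation: head = 5′ − 100 to 5′ + 50, tail = 3′ − 50 to
3′ + 100, middle between. Membership: the call's CI (its TSD for
two-breakpoint calls) intersects the region; "+" regions require matching
orientation, "−" opposite. The "upstream 200 bp" genic region is 200 bp 5′
of each transcript start, strand-aware.

## Synthetic data

The generator emulates exactly the features the pipeline consumes: an
i.i.d. background genome (uniform base composition; GC realism is a
non-goal at these scales) with planted fixed Alus — young AluYs at 1%
divergence flanked by perfect 6–16 bp TSDs (excisable by construction) and
older AluS copies at 10% — plus TPRT insertions with TSD ~ U{8..16},
poly-A ~ U{10..30}, no 5′ truncation with probability 0.8 else U{1..150}
(the literature constrains only the 4–25 bp TSD range; the rest are
documented fixture choices), strand Bernoulli(0.5), and nick sites drawn
uniformly or per a 6mer preference table using the same frame as the
estimator. Insertions are isolated by ≥ 500 bp so truth intervals never
interact. Reads are 100 bp FR pairs (insert 300 ± 30 by default) with
optional substitution errors, aligned by a *truth-guided mapper*: each
read's donor interval is intersected with the known donor↔reference shared
blocks, the longest shared piece becomes the aligned segment
(soft-clipping the rest, MAPQ 60), and reads with < 20 bp of shared
sequence are emitted unmapped. Tests are therefore hermetic and
deterministic; what they do *not* exercise is aligner-specific soft-clip
placement, base-quality effects, chimeras or PCR duplicates, so passing
them bounds algorithmic, not aligner, behaviour. A real-aligner adapter
can feed the same SAM interface.

Benchmark bundles: `tiny` (200 kb, 10 excisable AluYs + 10 decoys, 20×)
for CI-speed tests; `desk` (2 Mb, 100 + 100, 20×) for the calibration
experiment. These sizes keep the full calibration run in minutes on one
CPU while leaving ≥ 30 junction-spanning fragments per excision at 20×,
enough that the support grid (6–25) is meaningfully exercised.

## Numerical and degenerate-input choices

- All DP scores are integers; the vectorised horizontal-gap state uses a
  prefix-max scan that is exact because gap-open ≥ gap-extend.
- Quantiles use numpy's default interpolation; profiles with < 1000 proper
  templates warn and use all of them.
- Empty candidate sets, zero-excision worlds and empty segments are valid
  and return empty/zero results; an empty consensus library, a paired
  group with no mapped templates, use(s) > 0 with count(s) = 0, and
  p outside [0,1] raise.
- Cross-individual dedup keeps the first call in (chrom, start) order; the
  alternative (keep-most-support) was rejected to keep the subset
  independent of score scales.
- Trio screening matches by CI overlap ignoring strand (lenient: a strand
  requirement would manufacture de novo candidates from strand errors).
- Call-set comparison expands CIs to ≥ 20 bp (potential TSD) and treats
  interval overlap as closed at the boundary, so abutting breakpoint CIs
  of the same blunt insertion still match.

## Known limitations

- Inversions, 3′ transductions, nested insertions and non-Alu mobile
  elements are out of scope (the machinery is mechanically generic but the
  defaults and fixtures are Alu-oriented).
- No het/hom genotyping and no source-element tracing.
- Breakpoints at microhomologous junctions are reported at the leftmost
  equal-scoring position; the true position is unidentifiable from the
  data.
- The faux-reference experiment at desk scale uses error-free synthetic
  reads, so its operating point reflects clean-input behaviour; with real
  reads the same code path selects data-set-specific thresholds.
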