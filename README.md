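# aluscan

Detection of novel **Alu retrotransposon insertions** from paired
short-read mappings, with breakpoint and target-site-duplication (TSD)
resolution, simulation-based filter calibration, and a statistical model of
where new insertions land.

Alu elements are ~300 bp primate SINEs that multiply by target-primed
reverse transcription (TPRT): the L1 endonuclease nicks the genome,
reverse transcriptase copies the Alu RNA in situ, and repair duplicates
4–25 bp of the target site on both sides of the new element. A polymorphic
insertion absent from the reference shows up in sequencing data as
soft-clipped reads at the two junctions, discordant insert sizes, and
pairs with one unmapped mate. `aluscan` is for researchers calling such
insertions from WGS or exome-capture Illumina data — and for studying the
insertion process itself.

What it does:

- **Detection** — candidate fragments are clustered along the reference
  and each read is split-mapped with a Smith–Waterman DP that may jump
  from the reference into an Alu consensus and back. The jump out of the
  reference is the insertion start `b_start` (right end of the TSD), the
  jump back is the insertion end `b_end` (left end), and for a standard
  call the confidence interval (CI) is exactly the TSD with
  `tsd_len = b_start − b_end`.
- **Filter calibration by faux-reference simulation** — young reference
  AluYs (≥ 310 bp, perfect flanking TSD ≥ 6 bp) are computationally
  excised (reversing TPRT) and detection is re-run against the excised
  genome, turning every removed element into a known target. A
  10,500-point grid over the four filters (`len`, `supp`, `null`,
  `ci-len`) is scored on one unfiltered run and the setting maximising
  simulated recall subject to simulated precision ≥ x (default 0.97) is
  selected.
- **Endonuclease nick-site preferences** — for every 6mer *s*,
  `p(s) = use(s) / (n·count(s))`: the probability that a new insertion
  cuts at one specific site carrying *s* (`count` over the double-stranded
  genome). The derived placement model `D_nick` ("uniform modulo nick-site
  preferences") and the fully uniform `D_unif` drive single-sided exact
  binomial enrichment tests of genomic regions (exons, introns, the
  head/middle/tail neighbourhoods of existing Alus).
- **Evaluation utilities** — multi-set interval clustering (single
  linkage, since interval overlap is not transitive), relative
  precision/recall against external call sets, Mendelian trio screening,
  and coverage-window computation for WGS-vs-exome comparisons.
- **Synthetic data** — seeded generators for references with planted fixed
  Alus, TPRT insertions (nick sites drawn uniformly or per a 6mer
  preference table), and truth-aligned paired reads, so everything above
  is testable hermetically.

## Worked example

```bash
python examples/01_detect_insertions.py
```

builds a 120 kb synthetic reference, plants six insertions, simulates 18×
paired 100 bp reads and runs detection:

```
planted insertions (b_end, b_start, strand, tsd):
     3474    3482  -  8
    61531   61547  +  16
    ...

detected calls (1-based CI in the TSV export):
chrom  ci_start  ci_end strand  reads_left  reads_right  tsd_len breakpoints  inner_min  inner_max  supp  score_alu  score_null   family
 chr1      3475    3482      -          13           15        8   end,start          1        294    54     6894.0      1694.0 AluY_syn
 chr1     61532   61547      +          10           14       16   end,start          1        297    47     6086.0      1566.0 AluY_syn
 ...
```

Each call's CI (1-based inclusive on output; internally 0-based half-open,
so `3475–3482` is the planted `[3474, 3482)`) is exactly the planted TSD;
`reads_left`/`reads_right` count reads spanning the two junctions;
`inner_min`/`inner_max` give the consensus span covered; `supp` is the
supporting fragment count; `score_alu` vs `score_null` compares the
insertion hypothesis with mapping all reads to the reference only.

The other examples each run one capability end to end:
`02_filter_calibration.py` (faux-reference grid search),
`03_nick_preferences.py` (preference-table estimation, recovering a
planted model), `04_enrichment_testing.py` (binomial region tests and the
whole-genome normalisation of `D_nick`), `05_trio_screen.py` (de novo
candidate screening in a simulated trio).

A thin CLI wraps the same library calls for shell use:

```bash
aluscan simulate --scale tiny --seed 2 -o sim/
aluscan detect --reference sim/faux_reference.fa --alignments sim/reads.sam \
               --consensus sim/consensus.fa -o det/
aluscan select-filter --calls det/calls_unfiltered.tsv \
                      --truth sim/truth_tsd.bed -x 0.97 -o sel/
```

Every run writes a `manifest.json` with the command, parameters and seeds.

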