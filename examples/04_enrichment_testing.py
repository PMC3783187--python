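"""Test genomic regions for insertion enrichment or depletion.

Compares observed insertion counts in a region against the expectation
under two placement models — D_unif (fully uniform) and D_nick (uniform
modulo 6mer nick preferences) — with a single-sided exact binomial test.
The example reproduces the coding-sequence style computation: 0 observed
insertions against an expectation of 11.0 out of 961 trials.
"""

from aluscan.models import AluCallRecord
from aluscan.nicksites import (
    InsertionModel, count_6mers, enrichment_test, nick_usage,
    preference_table)
from aluscan.synthetic import make_reference, plant_insertions

# the published-scale arithmetic: printed as "0.000"
r = enrichment_test(obs=0, n=961, p_region=11.0 / 961, region="coding")
print(f"coding sequence: obs={r.obs} expected={r.expected:.1f} "
      f"{r.direction} p={r.p_value:.2e}")

# a model-driven segment probability on a synthetic genome
reference, _, library = make_reference(seed=17, length=400_000,
                                       n_fixed_alus=0)
world = plant_insertions(reference, library, 300, "uniform", seed=23,
                         min_sep=600)
calls = [AluCallRecord("chr1", i.b_end, i.b_start, i.strand,
                       breakpoints=frozenset({"start", "end"}),
                       tsd_len=i.tsd_len, supp=2)
         for i in world.insertions]
table = preference_table(nick_usage(calls, reference),
                         count_6mers(reference), len(calls))
dnick = InsertionModel("D_nick", reference, table)
dunif = InsertionModel("D_unif", reference)

segment = ("chr1", 100_000, 150_000)
obs_in_segment = sum(100_000 <= c.ci_end <= 150_000 for c in calls)
for name, model in (("D_unif", dunif), ("D_nick", dnick)):
    p = model.segment_probability(*segment)
    res = enrichment_test(obs_in_segment, len(calls), p, region="50 kb")
    print(f"{name}: p_region={p:.4f} obs={res.obs} "
          f"expected={res.expected:.1f} {res.direction} "
          f"p={res.p_value:.3f}")
print(f"whole-genome mass under D_nick: "
      f"{dnick.whole_genome_probability():.9f} (must be 1)")
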