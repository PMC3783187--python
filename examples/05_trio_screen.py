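"""Screen a child's calls against both parents for de novo candidates.

Simulates a trio in which the parents share three insertions and the child
carries one extra.  Child calls are screened against the parents'
*unfiltered* (support >= 2) call sets: true inherited insertions vanish
even when a parent's call missed the filters, leaving only genuine de novo
candidates.
"""

from aluscan import detect_insertions
from aluscan.evaluation import mendelian_screen
from aluscan.synthetic import make_reference, plant_insertions, \
    simulate_reads

reference, _, library = make_reference(seed=3, length=120_000,
                                       n_fixed_alus=0)
child_world = plant_insertions(reference, library, 4, "uniform", seed=41,
                               avoid_microhomology=True,
                               tsd_dist=lambda r: 12,
                               trunc_dist=lambda r: 0)
nicks = [(i.nick, i.strand) for i in child_world.insertions]
parent_world = plant_insertions(reference, library, 3, "uniform", seed=41,
                                nicks=nicks[:-1], tsd_dist=lambda r: 12,
                                trunc_dist=lambda r: 0)

child_calls = detect_insertions(
    simulate_reads(child_world, coverage=15.0, seed=43), reference, library)
father_calls = detect_insertions(
    simulate_reads(parent_world, coverage=15.0, seed=44), reference, library)
mother_calls = detect_insertions(
    simulate_reads(parent_world, coverage=15.0, seed=45), reference, library)

candidates = mendelian_screen(child_calls, father_calls, mother_calls)
print(f"child calls: {len(child_calls)}; "
      f"parent calls: {len(father_calls)}/{len(mother_calls)}")
print("de novo candidates (should be exactly the one extra insertion):")
for c in candidates:
    print(f"  {c.chrom}:{c.ci_start}-{c.ci_end} {c.strand} "
          f"tsd={c.tsd_len} supp={c.supp}")
extra = child_world.insertions[-1]
print(f"planted extra insertion: {extra.b_end}-{extra.b_start} "
      f"{extra.strand}")
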