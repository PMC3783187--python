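import numpy as np
import pytest
from scipy import stats

from aluscan.models import AluCallRecord, ReferenceGenome, RepeatAnnotation, \
    RepeatRecord, SequenceRecord
from aluscan.nicksites import (
    ClearAlu,
    InsertionModel,
    clear_alus,
    count_6mers,
    enrichment_test,
    high_confidence_subset,
    kmer_code,
    kmer_string,
    nick_context,
    nick_usage,
    preference_table,
    region_membership,
)
from aluscan.synthetic import make_reference, plant_insertions

from oracles import binom_tail_enumeration, count_6mers_naive


def _genome(seq):
    return ReferenceGenome([SequenceRecord("chr1", seq)])


class TestCount6mers:
    def test_hand_case_both_strands(self):
        counts = count_6mers(_genome("TTAAAA"))
        assert counts[kmer_code("TTAAAA")] == 1
        assert counts[kmer_code("TTTTAA")] == 1
        assert counts.sum() == 2

    def test_homopolymer(self):
        counts = count_6mers(_genome("AAAAAAA"))
        assert counts[kmer_code("AAAAAA")] == 2
        assert counts[kmer_code("TTTTTT")] == 2

    def test_n_windows_skipped(self):
        counts = count_6mers(_genome("ACGTNACGTACG"))
        naive = count_6mers_naive("ACGTNACGTACG")
        assert counts.sum() == sum(naive.values())

    def test_matches_naive_scan(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        counts = count_6mers(_genome(seq))
        naive = count_6mers_naive(seq)
        assert counts.sum() == sum(naive.values())
        for kmer in ("TTAAAA", "ACGTAC", "GGGGGG", "TTTAAA"):
            assert counts[kmer_code(kmer)] == naive.get(kmer, 0)


def _call(chrom, ci, strand, bps=("start", "end"), inner=311, tsd=None):
    tsd_val = ci[1] - ci[0] if set(bps) == {"start", "end"} else tsd
    return AluCallRecord(chrom, ci[0], ci[1], strand,
                         breakpoints=frozenset(bps), tsd_len=tsd_val,
                         inner_min=1, inner_max=inner, supp=5,
                         score_alu=100.0, score_null=10.0)


class TestNickUsage:
    def test_plus_strand_reads_forward_context(self):
        # cut between TT and AAAA: b_start at offset 10
        seq = "GGGGGGGG" + "TT" + "AAAA" + "GGGGGGGGGG"
        g = _genome(seq)
        call = _call("chr1", (4, 10), "+")   # b_start = ci_end = 10
        use = nick_usage([call], g)
        assert use[kmer_code("TTAAAA")] == 1
        assert use.sum() == 1

    def test_minus_strand_reads_reverse_complement(self):
        # minus-strand nick at x reads rc(genome[x-4:x+2]): plant so that
        # rc(genome[6:12]) == TTAAAA, i.e. genome[6:12] == TTTTAA
        seq = "GGGGGG" + "TTTTAA" + "GGGGGGGG"
        g = _genome(seq)
        call = _call("chr1", (10, 16), "-")  # b_end = ci_start = 10
        use = nick_usage([call], g)
        assert use[kmer_code("TTAAAA")] == 1

    def test_strand_flip_same_6mer(self):
        """Mirrored constructions on opposite strands tally one 6mer."""
        fwd = "GGGGGGGG" + "TTAAAA" + "GGGGGG"
        from aluscan.align import revcomp
        g1 = _genome(fwd)
        g2 = _genome(revcomp(fwd))
        u1 = nick_usage([_call("chr1", (4, 10), "+")], g1)
        L = len(fwd)
        # mirrored call: b_end = L - 10
        u2 = nick_usage([_call("chr1", (L - 10, L - 4), "-")], g2)
        assert (u1 == u2).all()

    def test_call_without_needed_breakpoint_skipped(self):
        g = _genome("ACGTACGTACGTACGTACGT")
        assert nick_usage([_call("chr1", (4, 10), "+", bps=("end",))],
                          g).sum() == 0

    def test_edge_call_skipped_with_warning(self, caplog):
        g = _genome("ACGTACGTAC")
        with caplog.at_level("WARNING", "aluscan"):
            use = nick_usage([_call("chr1", (0, 1), "+")], g)
        assert use.sum() == 0
        assert "skipped" in caplog.text


# Printed preference rows: 6mer, use, count, p (1e-10 units), n = 961
PUBLISHED_N = 961
PUBLISHED_ROWS = [
    ("TTAAGA", 66, 2_288_139, 299.8),
    ("TTAAAA", 187, 6_962_385, 279.1),
    ("TTAGAA", 31, 2_649_151, 121.6),
    ("ATAAGA", 24, 2_079_719, 119.9),
    ("ATAAAA", 64, 6_336_702, 104.9),
    ("GTAAGA", 12, 1_291_580, 96.5),
    ("TTGAAA", 27, 3_520_814, 79.7),
    ("TTAAAG", 20, 2_683_435, 77.4),
    ("GTAAAA", 17, 2_572_529, 68.6),
    ("AGAATT", 17, 3_081_468, 57.3),
    ("CTAAAA", 18, 3_495_396, 53.5),
    ("AGAAAT", 21, 4_618_715, 47.2),
    ("TCAAAA", 19, 4_226_703, 46.7),
    ("AGAAAA", 30, 7_090_365, 43.9),
    ("AGAAAG", 15, 4_056_864, 38.4),
    ("ACAAAA", 20, 5_675_151, 36.6),
    ("ATGAAA", 13, 3_884_418, 34.7),
    ("TTAAAT", 11, 4_192_065, 27.2),
    ("TTTAAA", 10, 6_870_404, 15.1),
]


class TestPreferenceTable:
    def _table(self):
        use = np.zeros(4096, dtype=np.int64)
        count = np.zeros(4096, dtype=np.int64)
        for kmer, u, c, _ in PUBLISHED_ROWS:
            use[kmer_code(kmer)] = u
            count[kmer_code(kmer)] = c
        return preference_table(use, count, PUBLISHED_N)

    @pytest.mark.parametrize("kmer,u,c,printed", PUBLISHED_ROWS)
    def test_published_rows_within_one_percent(self, kmer, u, c, printed):
        """p(s) = use/(n*count) reproduces the published preferences."""
        t = self._table()
        assert t.p_of(kmer) * 1e10 == pytest.approx(printed, rel=0.01)

    def test_zero_use_zero_preference(self):
        t = self._table()
        assert t.p_of("CCCCCC") == 0.0

    def test_use_without_count_is_error(self):
        use = np.zeros(4096, dtype=np.int64)
        use[0] = 3
        with pytest.raises(ValueError, match="inconsistent"):
            preference_table(use, np.zeros(4096, dtype=np.int64), 10)

    def test_normalization_identity(self):
        """sum count(s) * p(s) = sum use(s)/n = 1 for a complete tally."""
        t = self._table()
        total_use = sum(u for _, u, _, _ in PUBLISHED_ROWS)
        assert float((t.count * t.p).sum()) == \
            pytest.approx(total_use / PUBLISHED_N, abs=1e-12)


class TestHighConfidenceSubset:
    def test_selection_criteria(self):
        keep = _call("chr1", (100, 110), "+")
        one_bp = _call("chr1", (300, 310), "+", bps=("start",), tsd=None)
        short_inner = _call("chr1", (500, 510), "+", inner=250)
        tsd50 = _call("chr1", (700, 750), "+")
        got = high_confidence_subset([[keep, one_bp, short_inner, tsd50]])
        assert got == [keep]

    def test_cross_individual_dedup(self):
        a = _call("chr1", (100, 110), "+")
        b = _call("chr1", (105, 113), "+")
        c = _call("chr1", (400, 410), "-")
        got = high_confidence_subset([[a], [b, c]])
        assert got == [a, c]


class TestInsertionModels:
    def test_uniform_toy_segment(self):
        g = _genome("A" * 100)
        m = InsertionModel("D_unif", g)
        assert m.segment_probability("chr1", 10, 20) == pytest.approx(0.1)
        assert m.whole_genome_probability() == pytest.approx(1.0)

    def test_empty_segment_zero(self):
        g = _genome("A" * 100)
        assert InsertionModel("D_unif", g).segment_probability(
            "chr1", 50, 50) == 0.0

    def _self_consistent_model(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 30_000))
        g = _genome(seq)
        # tally every valid plus/minus nick position once: by construction
        # this is a complete usage census, so total mass must be 1
        from aluscan.nicksites import kmer_codes_both_strands
        plus, minus = kmer_codes_both_strands(seq)
        use = np.zeros(4096, dtype=np.int64)
        for arr in (plus, minus):
            v = arr[arr >= 0]
            use += np.bincount(v, minlength=4096)
        n = int(use.sum())
        table = preference_table(use, count_6mers(g), n)
        return g, table

    def test_whole_genome_mass_is_one(self, rng):
        g, table = self._self_consistent_model(rng)
        m = InsertionModel("D_nick", g, table)
        assert m.whole_genome_probability() == pytest.approx(1.0, abs=1e-9)

    def test_partition_sums_to_whole_genome(self, rng):
        g, table = self._self_consistent_model(rng)
        m = InsertionModel("D_nick", g, table)
        L = g.length("chr1")
        cuts = [0, 137, 5000, 17_500, 29_000, L + 1]
        total = sum(m.segment_probability("chr1", a, b)
                    for a, b in zip(cuts, cuts[1:]))
        assert total == pytest.approx(m.whole_genome_probability(),
                                      abs=1e-12)

    def test_parameter_recovery_from_planted_insertions(self):
        """Insertions planted under a known preference table re-estimate
        preferences that rank-correlate with truth (rho >= 0.9) and
        recover the top 6mer."""
        ref, _, lib = make_reference(31, 900_000, 0)
        truth_pref = {"TTAAAA": 10.0, "TTAAGA": 9.0, "ATAAAA": 4.0,
                      "TTAGAA": 2.0, "GTAAGA": 1.5, "TCAAAA": 1.0}
        world = plant_insertions(ref, lib, 400, truth_pref, seed=5,
                                 min_sep=600)
        calls = [
            _call("chr1", (i.b_end, i.b_start), i.strand)
            for i in world.insertions]
        use = nick_usage(calls, ref)
        table = preference_table(use, count_6mers(ref), len(calls))
        est = np.array([table.p_of(k) for k in truth_pref])
        want = np.array(list(truth_pref.values()))
        rho = stats.spearmanr(est, want).statistic
        assert rho >= 0.9
        top_est = kmer_string(int(np.argmax(table.p)))
        assert top_est in ("TTAAAA", "TTAAGA")


class TestGenicRegions:
    GTF = (
        'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
        'chr1\tx\tCDS\t151\t200\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
        'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
        'chr1\tx\texon\t701\t800\t.\t-\t.\tgene_id "h"; transcript_id "t2";\n'
    )

    @pytest.fixture()
    def sets(self, tmp_path):
        from aluscan.io import read_gene_annotation
        from aluscan.nicksites import genic_region_sets

        p = tmp_path / "g.gtf"
        p.write_text(self.GTF)
        return genic_region_sets(read_gene_annotation(p))

    def test_partition_of_transcript_span(self, sets):
        assert sets["coding"]["chr1"] == [(150, 200)]
        assert sets["noncoding_exon"]["chr1"] == [(100, 150), (300, 400),
                                                  (700, 800)]
        assert sets["introns"]["chr1"] == [(200, 300)]
        assert sets["genes"]["chr1"] == [(100, 400), (700, 800)]

    def test_upstream_200_strand_aware(self, sets):
        # + transcript starts at 100 -> [0, 100) (clipped);
        # - transcript 5' end is its right edge 800 -> [800, 1000)
        assert sets["upstream_200"]["chr1"] == [(0, 100), (800, 1000)]

    def test_counts_and_probability(self, sets):
        from aluscan.nicksites import (
            InsertionModel, count_calls_in_regions, region_set_probability)

        g = _genome("A" * 1000)
        m = InsertionModel("D_unif", g)
        # genes cover 400 of 1000 positions per strand
        assert region_set_probability(m, sets["genes"]) == pytest.approx(0.4)
        calls = [_call("chr1", (120, 130), "+"),
                 _call("chr1", (500, 510), "+")]
        assert count_calls_in_regions(calls, sets["genes"]) == 1


class TestClearAlus:
    def _rec(self, start=10_000, end=10_311, strand="+", name="AluY",
             cons=(1, 311), chrom="chr1"):
        return RepeatRecord(chrom, start, end, strand, name, "SINE/Alu",
                            cons[0], cons[1])

    def test_isolated_full_length_is_clear(self):
        (ca,) = clear_alus(RepeatAnnotation([self._rec()]))
        assert ca.head == (10_000 - 100, 10_000 + 50)
        assert ca.middle == (10_000 + 50, 10_311 - 50)
        assert ca.tail == (10_311 - 50, 10_311 + 100)

    def test_nearby_sine_disqualifies(self):
        other = self._rec(start=10_461, end=10_700, name="MIR")
        assert clear_alus(RepeatAnnotation([self._rec(), other])) == []

    def test_truncated_annotation_excluded(self):
        assert clear_alus(RepeatAnnotation(
            [self._rec(cons=(50, 311))])) == []
        assert clear_alus(RepeatAnnotation(
            [self._rec(cons=(1, 250))])) == []

    def test_length_mismatch_excluded(self):
        rec = self._rec(end=10_000 + 380)   # 380 vs consensus span 311
        assert clear_alus(RepeatAnnotation([rec])) == []

    def test_minus_strand_head_on_right(self):
        (ca,) = clear_alus(RepeatAnnotation([self._rec(strand="-")]))
        assert ca.head == (10_311 - 50, 10_311 + 100)
        assert ca.tail == (10_000 - 100, 10_000 + 50)


class TestRegionMembership:
    HEAD = (900, 1050)

    def test_one_bp_overlap_same_strand(self):
        call = _call("chr1", (890, 901), "+")
        assert region_membership(call, self.HEAD, "+", "+")

    def test_opposite_strand_request(self):
        call = _call("chr1", (950, 960), "-")
        assert region_membership(call, self.HEAD, "+", "-")
        assert not region_membership(call, self.HEAD, "+", "+")

    def test_distant_call_not_member(self):
        call = _call("chr1", (2000, 2010), "+")
        assert not region_membership(call, self.HEAD, "+", "any")


class TestEnrichmentTest:
    def test_zero_observed_coding_depletion(self):
        """No insertions out of 961 when 11.0 are expected is depleted at
        p = (1-p)^961 ~ 1.6e-5 (printed as 0.000)."""
        r = enrichment_test(0, 961, 11.0 / 961)
        assert r.direction == "depleted"
        assert r.p_value == pytest.approx((1 - 11.0 / 961) ** 961, rel=1e-9)
        assert r.p_value == pytest.approx(1.6e-5, rel=0.05)

    def test_observation_at_expectation(self):
        r = enrichment_test(5, 10, 0.5)
        assert r.p_value >= 0.5

    def test_small_case_exact_enumeration(self):
        # upper tail of Binomial(10, 0.5) at 8: (45+10+1)/1024
        r = enrichment_test(8, 10, 0.5)
        assert r.direction == "enriched"
        assert r.p_value == pytest.approx(56 / 1024, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_enumeration_for_small_n(self, n, rng):
        for _ in range(20):
            p = float(rng.uniform(0.05, 0.95))
            obs = int(rng.integers(0, n + 1))
            r = enrichment_test(obs, n, p)
            want = binom_tail_enumeration(n, p, obs,
                                          upper=r.direction == "enriched")
            assert r.p_value == pytest.approx(want, rel=1e-9)

    def test_recall_correction_applied_to_observation(self):
        r = enrichment_test(20, 961, 0.02, correction_factor=1.15)
        assert r.obs == 23

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(1, 10, 1.5)
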