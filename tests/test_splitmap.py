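import numpy as np
import pytest

from aluscan.align import revcomp
from aluscan.evidence import AluHit, CandidateFragment, PairingProfile
from aluscan.models import MAXTSD, ReadRecord, Template
from aluscan.splitmap import (
    Cluster,
    ClusterSummary,
    build_confidence_interval,
    cluster_fragments,
    split_map_read,
    summarize_cluster,
)

from oracles import split_score_oracle


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


PROFILE = PairingProfile("rg", True, 200, 500, read_len=100)


def _cand(name, pos, strand="+", clip=(0, 0), chrom="chr1", mapq=60,
          hit_score=50, hit_strand="+", seq=None, read_len=100):
    r = ReadRecord(name=name, seq=seq or "A" * read_len, read_group="rg",
                   is_mapped=True, chrom=chrom, pos=pos, strand=strand,
                   clip_left=clip[0], clip_right=clip[1],
                   aligned_len=read_len - clip[0] - clip[1], mapq=mapq)
    c = CandidateFragment(Template(name, "rg", [r]), frozenset({"x"}))
    c.alu_hits = [AluHit(name, "AluY_syn", 0, 80, hit_strand, hit_score)]
    return c


class TestClustering:
    def test_nearby_anchors_merge(self):
        cands = [_cand("a", 1000), _cand("b", 1050)]
        (cl,) = cluster_fragments(cands, {"rg": PROFILE})
        assert len(cl.members) == 2

    def test_different_chroms_stay_apart_and_singletons_drop(self):
        cands = [_cand("a", 1000), _cand("b", 1000, chrom="chr2")]
        assert cluster_fragments(cands, {"rg": PROFILE}) == []

    def test_two_loci_two_clusters(self):
        """20 fragments around two loci 10 kb apart give exactly 2
        clusters (single-linkage oracle: gap >> frag_max)."""
        rng = np.random.default_rng(8)
        cands = [_cand(f"a{i}", 1000 + int(rng.integers(0, 80)))
                 for i in range(10)]
        cands += [_cand(f"b{i}", 11_000 + int(rng.integers(0, 80)))
                  for i in range(10)]
        clusters = cluster_fragments(cands, {"rg": PROFILE})
        assert len(clusters) == 2
        assert sorted(len(c.members) for c in clusters) == [10, 10]

    def test_consensus_chosen_by_summed_score(self):
        a = _cand("a", 1000, hit_score=30)
        b = _cand("b", 1040, hit_score=30)
        c = _cand("c", 1020)
        c.alu_hits = [AluHit("c", "AluSx_syn", 0, 80, "+", 100)]
        (cl,) = cluster_fragments([a, b, c], {"rg": PROFILE})
        assert cl.consensus == "AluSx_syn"


class TestSplitMapRead:
    def test_junction_at_construction_point(self, rng, library):
        """20 bp of reference followed by 20 bp of consensus: the jump is
        at the construction point with a full-score alignment."""
        window = _dna(rng, 120)
        cons = library.seq("AluY_syn")
        read = window[40:60] + cons[:20]
        a = split_map_read(read, window, cons, window_start=0)
        assert a.config == "ref_cons"
        assert a.score_split == 40
        assert a.junctions == [("start", 60)]

    def test_reference_only_read(self, rng):
        window = _dna(rng, 150)
        read = window[30:90]
        a = split_map_read(read, window, "G" * 260 + "A" * 40)
        assert a.config == "ref"
        assert a.score_split == a.score_ref_only == 60

    def test_two_junctions_recovered(self, rng, library):
        """A read spanning a short planted insertion with an 8 bp TSD
        recovers both junctions at the construction points."""
        window = _dna(rng, 200)
        cons = library.seq("AluY_syn")
        b_start, tsd = 100, 8
        b_end = b_start - tsd
        insert = cons[:60]
        # donor read: ref up to b_start, insert, then ref from b_end
        read = window[b_start - 30:b_start] + insert + \
            window[b_end:b_end + 30]
        a = split_map_read(read, window, cons, window_start=0)
        assert a.config == "ref_cons_ref"
        assert a.score_split == len(read)
        assert ("start", b_start) in a.junctions
        assert ("end", b_end) in a.junctions

    def test_matches_enumeration_oracle(self, rng, library):
        """Split DP equals brute-force enumeration over all split points
        and pairs on 60 random constructions."""
        cons_full = library.seq("AluY_syn")
        for trial in range(60):
            window = _dna(rng, int(rng.integers(60, 120)))
            cons = cons_full[:int(rng.integers(40, 70))]
            kind = trial % 4
            if kind == 0:
                read = _dna(rng, int(rng.integers(20, 40)))
            elif kind == 1:
                i = int(rng.integers(10, 25))
                read = window[5:5 + i] + cons[:int(rng.integers(10, 20))]
            elif kind == 2:
                i = int(rng.integers(10, 20))
                read = cons[10:10 + i] + window[40:40 + int(rng.integers(10, 20))]
            else:
                read = window[60:75] + cons[:12] + window[20:35]
            got = split_map_read(read, window, cons).score_split
            want = split_score_oracle(read, window, cons)
            assert got == want, (trial, read, got, want)


class TestSummarize:
    def _cluster_with_reads(self, rng, library, n_span=2):
        window = _dna(rng, 300)
        cons = library.seq("AluY_syn")
        b = 150
        members = []
        for i in range(n_span):
            read = window[b - 40:b] + cons[:60]
            r = ReadRecord(name=f"s{i}", seq=read, read_group="rg",
                           is_mapped=True, chrom="chr1", pos=b - 40,
                           strand="+", clip_right=60, aligned_len=40,
                           mapq=60)
            c = CandidateFragment(Template(f"s{i}", "rg", [r]),
                                  frozenset({"partial_mapping"}))
            c.alu_hits = [AluHit(f"s{i}", "AluY_syn", 0, 60, "+", 60)]
            members.append(c)
        cl = Cluster("chr1", 0, 300, members, "AluY_syn", "+",
                     [(b - 25, b + 25)] * n_span)
        return cl, cons, window, b

    def test_shared_junction_counted(self, rng, library):
        cl, cons, window, b = self._cluster_with_reads(rng, library)
        s = summarize_cluster(cl, cons, window)
        assert s.supp == 2
        assert s.bp_start == b
        assert s.reads_left == 2
        assert s.score_alu > s.score_null

    def test_inner_span_extrema(self, rng, library):
        cl, cons, window, b = self._cluster_with_reads(rng, library)
        # add a read covering a distal consensus chunk
        read = cons[200:280]
        r = ReadRecord(name="deep", seq=read, read_group="rg")
        c = CandidateFragment(Template("deep", "rg", [r]),
                              frozenset({"one_end_unmapped"}))
        c.alu_hits = [AluHit("deep", "AluY_syn", 200, 280, "+", 80)]
        cl.members.append(c)
        cl.implied.append((b - 25, b + 25))
        s = summarize_cluster(cl, cons, window)
        assert s.inner_min == 1
        assert s.inner_max == 280

    def test_reference_reads_give_no_support(self, rng, library):
        """When every read is pure reference the cluster has supp 0 and no
        call is emitted."""
        from aluscan.splitmap import call_from_summary

        window = _dna(rng, 300)
        cons = library.seq("AluY_syn")
        members = []
        for i in range(3):
            read = window[50 + i * 20:150 + i * 20]
            r = ReadRecord(name=f"r{i}", seq=read, read_group="rg",
                           is_mapped=True, chrom="chr1", pos=50 + i * 20,
                           strand="+", clip_right=20, aligned_len=80,
                           mapq=60)
            c = CandidateFragment(Template(f"r{i}", "rg", [r]),
                                  frozenset({"partial_mapping"}))
            c.alu_hits = [AluHit(f"r{i}", "AluY_syn", 0, 20, "+", 20)]
            members.append(c)
        cl = Cluster("chr1", 0, 300, members, "AluY_syn", "+",
                     [(100, 200)] * 3)
        s = summarize_cluster(cl, cons, window)
        assert s.supp == 0
        assert call_from_summary(s) is None


def _summary(bp_start=None, bp_end=None, implied=None):
    cl = Cluster("chr1", 0, 1000, [], "AluY_syn", "+",
                 implied or [(100, 400)])
    return ClusterSummary(cl, 100.0, 50.0, 3, 1, 300, bp_start, bp_end,
                          2 if bp_start else 0, 2 if bp_end else 0)


class TestConfidenceIntervals:
    def test_two_breakpoints_ci_is_tsd_span(self):
        s, e, tsd, bps = build_confidence_interval(_summary(110, 100))
        assert (s, e, tsd) == (100, 110, 10)
        assert bps == {"start", "end"}

    def test_target_site_loss_negative_tsd(self):
        s, e, tsd, _ = build_confidence_interval(_summary(100, 104))
        assert (s, e, tsd) == (100, 104, -4)

    def test_blunt_insertion_zero_length_ci(self):
        s, e, tsd, _ = build_confidence_interval(_summary(100, 100))
        assert (s, e, tsd) == (100, 100, 0)

    def test_start_only_extends_upstream(self):
        s, e, tsd, bps = build_confidence_interval(_summary(bp_start=200))
        assert (s, e) == (200 - MAXTSD, 200)
        assert tsd is None and bps == {"start"}

    def test_end_only_extends_downstream(self):
        s, e, _, bps = build_confidence_interval(_summary(bp_end=200))
        assert (s, e) == (200, 200 + MAXTSD)
        assert bps == {"end"}

    def test_no_breakpoints_intersection(self):
        s, e, _, bps = build_confidence_interval(
            _summary(implied=[(100, 400), (250, 600)]))
        assert (s, e) == (250, 400)
        assert bps == frozenset()

    def test_empty_intersection_falls_back_to_widest(self):
        s, e, _, _ = build_confidence_interval(
            _summary(implied=[(100, 200), (300, 700)]))
        assert (s, e) == (300, 700)

    @pytest.mark.parametrize("tsd", [0, 4, 12, 25])
    def test_one_sided_detections_of_same_insertion_overlap(self, tsd):
        """Two independent detections of one insertion (start-only vs
        end-only) always produce overlapping CIs for usual TSDs."""
        b_start = 500
        b_end = b_start - tsd
        s1, e1, _, _ = build_confidence_interval(_summary(bp_start=b_start))
        s2, e2, _, _ = build_confidence_interval(_summary(bp_end=b_end))
        # closed-interval overlap, the convention used when matching calls
        assert s1 <= e2 and s2 <= e1
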