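"""End-to-end detection: evidence gathering, clustering, split mapping and
call construction (pipeline steps i-vi minus filtering, which callers apply
separately so the faux-reference grid can reuse one unfiltered run)."""

from __future__ import annotations

import logging

from .align import GenomeIndex
from .evidence import (
    extract_candidates,
    find_alu_evidence,
    infer_pairing_profile,
    progressive_remap,
    retain_by_mapq,
)
from .models import AluConsensusLibrary, ReferenceGenome
from .splitmap import WINDOW_MAX, call_from_summary, cluster_fragments, \
    summarize_cluster

log = logging.getLogger("aluscan")


def detect_insertions(templates, reference: ReferenceGenome,
                      library: AluConsensusLibrary,
                      profiles=None, mapq_min: int = 5,
                      remap_unmapped: bool = False,
                      genome_index: GenomeIndex | None = None):
    """Produce the unfiltered call set (support >= 2 fragments).

    ``remap_unmapped`` enables progressive trim-and-remap for candidate
    templates that would otherwise have no anchor of MAPQ >= ``mapq_min``;
    with mappings that already include soft-clipped alignments (any modern
    aligner, or the truth-guided simulator) this rescues nothing and is off
    by default.
    """
    templates = list(templates)
    if profiles is None:
        profiles = infer_pairing_profile(templates)
    candidates = extract_candidates(templates, profiles)
    log.info("%d candidate fragments", len(candidates))
    if remap_unmapped:
        index = genome_index or GenomeIndex(reference)
        for cand in candidates:
            if any(r.is_mapped and r.mapq >= mapq_min
                   for r in cand.template.reads):
                continue
            for r in cand.template.reads:
                if r.is_mapped:
                    continue
                rm = progressive_remap(r, index)
                if rm.is_mapped:
                    m = rm.mapping
                    r.is_mapped = True
                    r.chrom = m["chrom"]
                    r.pos = m["pos"]
                    r.strand = m["strand"]
                    r.mapq = m["mapq"]
                    r.clip_left = rm.trim_5 + m["q_start"]
                    r.clip_right = (len(m["seq_oriented"]) - m["q_end"]) + rm.trim_3
                    r.aligned_len = m["q_end"] - m["q_start"]
                    break
    candidates = retain_by_mapq(candidates, mapq_min)
    candidates = find_alu_evidence(candidates, library)
    log.info("%d fragments with consensus evidence", len(candidates))
    clusters = cluster_fragments(candidates, profiles)
    log.info("%d clusters", len(clusters))
    calls = []
    for cl in clusters:
        window = reference.fetch(cl.chrom, max(0, cl.window_start),
                                 cl.window_end)
        ws = max(0, cl.window_start)
        cl.window_start = ws
        summary = summarize_cluster(cl, library.seq(cl.consensus), window)
        call = call_from_summary(summary)
        if call is not None:
            calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.ci_start, c.ci_end))
    return calls
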