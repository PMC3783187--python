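"""Readers and writers for every external format the pipeline touches.

FASTA via Biopython, SAM/BAM via pysam, GTF/GFF3 via gffutils, call tables
via pandas.  All coordinates are normalised to 0-based half-open on read and
converted back to the format's native convention on write.
"""

from __future__ import annotations

import logging
import os
import warnings
from collections import OrderedDict

import pandas as pd
from Bio import SeqIO

from .models import (
    AluCallRecord,
    AluConsensusLibrary,
    FormatError,
    ReadRecord,
    ReferenceGenome,
    RepeatAnnotation,
    RepeatRecord,
    SequenceRecord,
    Template,
    Transcript,
)

log = logging.getLogger("aluscan")

_VALID_FASTA = set("ACGTN")


def _validate_fasta_records(path, records):
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_FASTA
        if bad:
            line = _find_bad_line(path, bad)
            raise FormatError(
                f"{path}: non-IUPAC character(s) {sorted(bad)} in record "
                f"{rec.id!r} (line {line})"
            )
        out.append(SequenceRecord(rec.id, seq))
    if not out:
        raise FormatError(f"{path}: empty FASTA file")
    return out


def _find_bad_line(path, bad_chars):
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith(">"):
                    continue
                if set(line.strip().upper()) & bad_chars:
                    return lineno
    except OSError:
        pass
    return "?"


def read_fasta(path) -> ReferenceGenome:
    """Read a reference genome FASTA (uppercased, order preserved)."""
    return ReferenceGenome(_validate_fasta_records(path, SeqIO.parse(path, "fasta")))


def read_consensus_fasta(path) -> AluConsensusLibrary:
    """Read an Alu consensus library FASTA (entries 250-400 bp)."""
    return AluConsensusLibrary(_validate_fasta_records(path, SeqIO.parse(path, "fasta")))


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------

def _record_from_pysam(aln, header) -> ReadRecord:
    clip_left = clip_right = 0
    aligned = 0
    if not aln.is_unmapped and aln.cigartuples:
        ct = aln.cigartuples
        if ct[0][0] in (4, 5):
            clip_left = ct[0][1]
        if len(ct) > 1 and ct[-1][0] in (4, 5):
            clip_right = ct[-1][1]
        aligned = sum(l for op, l in ct if op in (0, 7, 8, 2))  # ref-consuming
    try:
        rg = aln.get_tag("RG")
    except KeyError:
        rg = "default"
    return ReadRecord(
        name=aln.query_name,
        seq=(aln.query_sequence or ""),
        read_group=rg,
        is_mapped=not aln.is_unmapped,
        chrom=aln.reference_name if not aln.is_unmapped else "",
        pos=aln.reference_start if not aln.is_unmapped else -1,
        strand="-" if aln.is_reverse else "+",
        clip_left=clip_left,
        clip_right=clip_right,
        aligned_len=aligned,
        mapq=aln.mapping_quality,
        is_paired=aln.is_paired,
        is_read1=not aln.is_paired or aln.is_read1,
        mate_mapped=aln.is_paired and not aln.mate_is_unmapped,
        mate_chrom=(aln.next_reference_name or "") if aln.is_paired and not aln.mate_is_unmapped else "",
        mate_pos=aln.next_reference_start if aln.is_paired and not aln.mate_is_unmapped else -1,
        mate_strand="-" if (aln.is_paired and aln.mate_is_reverse) else "+",
        tlen=aln.template_length,
    )


def read_alignments(path, region=None):
    """Yield Templates (reads grouped by name + read group) from SAM/BAM.

    Requires a header.  Secondary and supplementary records are skipped.
    Records without a read group are assigned ``default`` with a warning.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        if not fh.header.to_dict():
            raise FormatError(f"{path}: missing SAM header")
        groups: "OrderedDict[tuple, Template]" = OrderedDict()
        warned = False
        try:
            it = fh.fetch(region=region) if region else iter(fh)
        except NotImplementedError as exc:
            raise FormatError(f"{path}: missing SAM header") from exc
        for aln in it:
            if aln.is_secondary or aln.is_supplementary:
                continue
            rec = _record_from_pysam(aln, fh.header)
            if rec.read_group == "default" and not warned:
                try:
                    aln.get_tag("RG")
                except KeyError:
                    log.warning("%s: records without read group assigned to "
                                "'default'", path)
                    warned = True
            key = (rec.name, rec.read_group)
            if key not in groups:
                groups[key] = Template(rec.name, rec.read_group)
            groups[key].reads.append(rec)
    yield from groups.values()


def write_alignments(templates, path, chrom_lengths: dict[str, int]) -> None:
    """Write templates as a coordinate-unsorted SAM file."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": l} for n, l in chrom_lengths.items()],
        "RG": [{"ID": rg} for rg in sorted({t.read_group for t in templates})],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for t in templates:
            for r in t.reads:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.name
                a.query_sequence = r.seq
                flag = 0
                if r.is_paired:
                    flag |= 0x1 | 0x2 * 0
                    flag |= 0x40 if r.is_read1 else 0x80
                    if not r.mate_mapped:
                        flag |= 0x8
                    elif r.mate_strand == "-":
                        flag |= 0x20
                if not r.is_mapped:
                    flag |= 0x4
                elif r.strand == "-":
                    flag |= 0x10
                a.flag = flag
                if r.is_mapped:
                    a.reference_name = r.chrom
                    a.reference_start = r.pos
                    a.mapping_quality = r.mapq
                    cig = []
                    if r.clip_left:
                        cig.append((4, r.clip_left))
                    cig.append((0, r.aligned_len))
                    if r.clip_right:
                        cig.append((4, r.clip_right))
                    a.cigartuples = cig
                if r.is_paired and r.mate_mapped:
                    a.next_reference_name = r.mate_chrom
                    a.next_reference_start = r.mate_pos
                    a.template_length = r.tlen
                a.set_tag("RG", r.read_group)
                out.write(a)


# ---------------------------------------------------------------------------
# Repeat annotations
# ---------------------------------------------------------------------------

def read_repeat_annotation(path, dialect: str = "auto") -> RepeatAnnotation:
    """Parse RepeatMasker ``.out`` or BED6+ repeat tables.

    RepeatMasker rows are 1-based inclusive and use ``C`` for the minus
    strand; both are normalised.  BED6+ expects
    chrom start end name score strand [class cons_start cons_end].
    """
    if dialect == "auto":
        dialect = _sniff_repeat_dialect(path)
    records = []
    with open(path) as fh:
        for idx, line in enumerate(fh):
            fields = line.split()
            if not fields:
                continue
            if dialect == "rmout":
                if not fields[0].replace(".", "").isdigit():
                    continue  # header lines
                chrom, qb, qe = fields[4], int(fields[5]), int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                name, rclass = fields[9], fields[10]
                if strand == "+":
                    cb, ce = int(fields[11]), int(fields[12])
                else:  # C rows print (left) begin end
                    cb, ce = int(fields[13]), int(fields[12])
                start, end = qb - 1, qe
            else:
                if fields[0].startswith(("#", "track")):
                    continue
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "repeat"
                strand = fields[5] if len(fields) > 5 else "+"
                if strand == "C":
                    strand = "-"
                rclass = fields[6] if len(fields) > 6 else ""
                cb = int(fields[7]) if len(fields) > 7 else 0
                ce = int(fields[8]) if len(fields) > 8 else 0
            if start >= end:
                raise FormatError(f"{path}: record {idx}: start >= end")
            records.append(RepeatRecord(chrom, start, end, strand, name,
                                        rclass, cb, ce))
    return RepeatAnnotation(records)


def _sniff_repeat_dialect(path) -> str:
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            if f[0] in ("SW", "score") or "perc" in line:
                return "rmout"
            if f[0].replace(".", "").isdigit() and len(f) >= 14:
                return "rmout"
            return "bed"
    return "bed"


def write_repeat_bed(annotation: RepeatAnnotation, path) -> None:
    with open(path, "w") as fh:
        for r in annotation:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.repeat_name}\t0\t"
                     f"{r.strand}\t{r.repeat_class}\t{r.consensus_start}\t"
                     f"{r.consensus_end}\n")


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

class GeneAnnotation:
    """Transcript models with a per-locus label function.

    A base is 'coding' if it is within CDS of any transcript; otherwise
    'noncoding_exon' if within an exon of any transcript; otherwise 'intron'
    if within any transcript span; otherwise 'intergenic'.
    """

    def __init__(self, transcripts: list[Transcript]):
        self.transcripts = transcripts
        self._cds: dict[str, list[tuple[int, int]]] = {}
        self._exon: dict[str, list[tuple[int, int]]] = {}
        self._span: dict[str, list[tuple[int, int]]] = {}
        for t in transcripts:
            for s, e in t.cds:
                self._cds.setdefault(t.chrom, []).append((s, e))
            for s, e in t.exons:
                self._exon.setdefault(t.chrom, []).append((s, e))
            if t.exons:
                self._span.setdefault(t.chrom, []).append(
                    (t.exons[0][0], t.exons[-1][1]))
        for d in (self._cds, self._exon, self._span):
            for c in d:
                d[c] = _merge_intervals(d[c])

    @staticmethod
    def _hit(ivs, pos):
        import bisect
        if not ivs:
            return False
        i = bisect.bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    def label(self, chrom: str, pos: int) -> str:
        if self._hit(self._cds.get(chrom), pos):
            return "coding"
        if self._hit(self._exon.get(chrom), pos):
            return "noncoding_exon"
        if self._hit(self._span.get(chrom), pos):
            return "intron"
        return "intergenic"

    def merged(self, kind: str) -> dict[str, list[tuple[int, int]]]:
        return {"cds": self._cds, "exon": self._exon,
                "span": self._span}[kind]


def _merge_intervals(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_gene_annotation(path) -> GeneAnnotation:
    """Read GTF/GFF3 transcript models (exon and CDS features)."""
    import gffutils

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            disable_infer_transcripts=True, disable_infer_genes=True,
        )
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        txids = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        if not txids:
            continue
        for txid in txids:
            d = by_tx.setdefault(txid, {
                "chrom": feat.seqid, "strand": feat.strand or "+",
                "gene": (feat.attributes.get("gene_id") or [txid])[0],
                "exons": [], "cds": []})
            iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
            d["exons" if feat.featuretype == "exon" else "cds"].append(iv)
    transcripts = []
    for txid, d in by_tx.items():
        if not d["exons"]:
            log.warning("transcript %s has no exons; skipped", txid)
            continue
        transcripts.append(Transcript(
            txid, d["gene"], d["chrom"], d["strand"],
            tuple(sorted(d["exons"])), tuple(sorted(d["cds"]))))
    return GeneAnnotation(transcripts)


# ---------------------------------------------------------------------------
# Call tables
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "chrom", "ci_start", "ci_end", "strand", "reads_left", "reads_right",
    "tsd_len", "breakpoints", "inner_min", "inner_max", "supp",
    "score_alu", "score_null", "family",
]


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        bps = ",".join(sorted(c.breakpoints)) if c.breakpoints else "none"
        rows.append({
            "chrom": c.chrom,
            "ci_start": c.ci_start + 1,  # 1-based inclusive export
            "ci_end": c.ci_end,
            "strand": c.strand,
            "reads_left": c.reads_left,
            "reads_right": c.reads_right,
            "tsd_len": c.tsd_len if c.tsd_len is not None else "",
            "breakpoints": bps,
            "inner_min": c.inner_min,
            "inner_max": c.inner_max,
            "supp": c.supp,
            "score_alu": c.score_alu,
            "score_null": c.score_null,
            "family": c.family,
        })
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(calls, path, format: str = "tsv") -> None:
    """Write calls as TSV (1-based inclusive CI) or BED (CI as interval)."""
    if format == "tsv":
        calls_to_frame(calls).to_csv(path, sep="\t", index=False)
    elif format == "bed":
        with open(path, "w") as fh:
            for c in calls:
                fh.write(f"{c.chrom}\t{c.ci_start}\t{c.ci_end}\t{c.family}\t"
                         f"{c.supp}\t{c.strand}\n")
    else:
        raise ValueError(f"unknown call format {format!r}")


def read_calls(path) -> list[AluCallRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    calls = []
    for _, row in df.iterrows():
        bp = frozenset() if row["breakpoints"] in ("none", "") else \
            frozenset(str(row["breakpoints"]).split(","))
        tsd = row["tsd_len"]
        tsd = None if tsd == "" else int(tsd)
        calls.append(AluCallRecord(
            chrom=row["chrom"],
            ci_start=int(row["ci_start"]) - 1,
            ci_end=int(row["ci_end"]),
            strand=row["strand"],
            reads_left=int(row["reads_left"]),
            reads_right=int(row["reads_right"]),
            tsd_len=tsd,
            breakpoints=bp,
            inner_min=int(row["inner_min"]),
            inner_max=int(row["inner_max"]),
            supp=int(row["supp"]),
            score_alu=float(row["score_alu"]),
            score_null=float(row["score_null"]),
            family=str(row["family"]),
        ))
    return calls


def read_bed_intervals(path):
    """Read BED-like intervals as (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f or f[0].startswith(("#", "track")):
                continue
            out.append((f[0], int(f[1]), int(f[2])))
    return out
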