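"""Shared domain types for the Alu-insertion calling pipeline.

Coordinate convention: every interval held in memory is 0-based, half-open
``[start, end)``.  Breakpoints and endonuclease nick sites are *between-base*
positions: position ``b`` sits between genome offsets ``b-1`` and ``b``.
Exported tables convert to 1-based inclusive coordinates on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")
#: TSDs produced by target-primed reverse transcription are almost never
#: longer than this; used to extend one-breakpoint confidence intervals.
MAXTSD = 25


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    name: str
    seq: str


class ReferenceGenome:
    """Ordered collection of chromosome sequences (uppercase A/C/G/T/N)."""

    def __init__(self, records: list[SequenceRecord]):
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate record name(s): {', '.join(dup)}")
        for r in records:
            if len(r.seq) == 0:
                raise FormatError(f"record {r.name!r} has empty sequence")
        self.records = list(records)
        self._by_name = {r.name: r for r in self.records}

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def seq(self, name: str) -> str:
        return self._by_name[name].seq

    def length(self, name: str) -> int:
        return len(self._by_name[name].seq)

    def fetch(self, name: str, start: int, end: int) -> str:
        return self._by_name[name].seq[max(0, start):end]


class AluConsensusLibrary:
    """Alu consensus sequences (~300 bp, optionally with appended poly-A)."""

    MIN_LEN, MAX_LEN = 250, 400

    def __init__(self, records: list[SequenceRecord]):
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            raise FormatError("duplicate consensus names")
        if not records:
            raise FormatError("empty consensus library")
        for r in records:
            if not (self.MIN_LEN <= len(r.seq) <= self.MAX_LEN):
                raise FormatError(
                    f"consensus {r.name!r} length {len(r.seq)} outside "
                    f"[{self.MIN_LEN}, {self.MAX_LEN}]"
                )
        self.records = list(records)
        self._by_name = {r.name: r for r in self.records}

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def seq(self, name: str) -> str:
        return self._by_name[name].seq


@dataclass(frozen=True)
class RepeatRecord:
    """One repeat-annotation row, 0-based half-open genome interval.

    ``consensus_start``/``consensus_end`` are 1-based inclusive positions on
    the repeat consensus, following RepeatMasker conventions.
    """

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str
    consensus_start: int = 0
    consensus_end: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"repeat record {self.repeat_name} has invalid interval "
                f"({self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def head_pos(self) -> int:
        """Genome position of the element 5' end (between-base)."""
        return self.start if self.strand == "+" else self.end

    def tail_pos(self) -> int:
        """Genome position of the element 3' end (between-base)."""
        return self.end if self.strand == "+" else self.start


class RepeatAnnotation:
    def __init__(self, records: list[RepeatRecord]):
        self.records = sorted(records, key=lambda r: (r.chrom, r.start, r.end))

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def alus(self) -> list[RepeatRecord]:
        return [r for r in self.records if r.repeat_class.startswith("SINE/Alu")
                or r.repeat_name.startswith("Alu")]

    def sines(self) -> list[RepeatRecord]:
        return [r for r in self.records if r.repeat_class.startswith("SINE")
                or r.repeat_name.startswith("Alu")]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]      # 0-based half-open, sorted
    cds: tuple[tuple[int, int], ...] = ()


@dataclass
class AluCallRecord:
    """One Alu insertion call.

    The confidence interval ``[ci_start, ci_end)`` brackets the target-site
    duplication.  When both breakpoints are detected its length equals
    ``|tsd_len|`` (0 for blunt insertions); ``tsd_len < 0`` records a target
    site loss.  ``breakpoints`` names the detected junction sides.
    """

    chrom: str
    ci_start: int
    ci_end: int
    strand: str
    reads_left: int = 0
    reads_right: int = 0
    tsd_len: int | None = None
    breakpoints: frozenset = frozenset()
    inner_min: int = 0
    inner_max: int = 0
    supp: int = 0
    score_alu: float = 0.0
    score_null: float = 0.0
    family: str = ""

    def __post_init__(self):
        if self.ci_start > self.ci_end:
            raise ValueError("ci_start > ci_end")
        if not self.breakpoints <= {"start", "end"}:
            raise ValueError(f"bad breakpoints {self.breakpoints}")
        self.breakpoints = frozenset(self.breakpoints)

    @property
    def ci_len(self) -> int:
        return self.ci_end - self.ci_start

    @property
    def inner_len(self) -> int:
        return self.inner_max - self.inner_min + 1 if self.inner_max else 0

    @property
    def null_gap_pct(self) -> float:
        if self.score_alu <= 0:
            return 0.0
        return 100.0 * (self.score_alu - self.score_null) / self.score_alu

    def overlaps(self, start: int, end: int) -> bool:
        return self.ci_start < end and start < self.ci_end


@dataclass(slots=True)
class ReadRecord:
    """One read with (optional) reference mapping, SAM-like semantics.

    ``seq`` is stored in reference-forward orientation when mapped (as in a
    SAM file); for unmapped reads it is the sequenced orientation.  ``pos`` is
    the 0-based leftmost aligned reference position; ``clip_left`` and
    ``clip_right`` are soft-clipped lengths flanking ``aligned_len`` matched
    bases.
    """

    name: str
    seq: str
    read_group: str = "default"
    is_mapped: bool = False
    chrom: str = ""
    pos: int = -1
    strand: str = "+"
    clip_left: int = 0
    clip_right: int = 0
    aligned_len: int = 0
    mapq: int = 0
    is_paired: bool = False
    is_read1: bool = True
    mate_mapped: bool = False
    mate_chrom: str = ""
    mate_pos: int = -1
    mate_strand: str = "+"
    tlen: int = 0

    @property
    def end(self) -> int:
        """Rightmost aligned reference position (exclusive)."""
        return self.pos + self.aligned_len

    @property
    def max_clip(self) -> int:
        return max(self.clip_left, self.clip_right)


@dataclass
class Template:
    """All reads sharing a template (query) name and read group."""

    name: str
    read_group: str
    reads: list[ReadRecord] = field(default_factory=list)

    @property
    def max_mapq(self) -> int:
        return max((r.mapq for r in self.reads if r.is_mapped), default=0)
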