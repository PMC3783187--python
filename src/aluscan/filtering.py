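"""Call filters: inner length (len), fragment support (supp), score gap
over the null hypothesis (null), CI length (ci-len), and the
non-ambiguous-breakpoint rule for calls overlapping reference Alus.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .models import MAXTSD, AluCallRecord, RepeatAnnotation


@dataclass(frozen=True)
class FilterSettings:
    """Thresholds for the four call filters.

    ``min_null_gap_pct`` is the relative score improvement required of the
    insertion hypothesis: (score_alu - score_null) >= pct/100 * score_alu.
    """

    min_inner_len: int = 0
    min_supp: int = 2
    min_null_gap_pct: float = 0.0
    max_ci_len: float = float("inf")

    def __post_init__(self):
        if self.min_supp < 2:
            raise ValueError("min_supp must be >= 2 (unfiltered floor)")
        if min(self.min_inner_len, self.min_null_gap_pct) < 0:
            raise ValueError("thresholds must be non-negative")


UNFILTERED = FilterSettings()

_SETTING_KEYS = {
    "min_inner_len": int, "min_supp": int, "min_null_gap_pct": float,
    "max_ci_len": float,
    # short aliases matching the CLI flag names
    "len": int, "supp": int, "null": float, "ci-len": float,
}
_ALIASES = {"len": "min_inner_len", "supp": "min_supp",
            "null": "min_null_gap_pct", "ci-len": "max_ci_len"}


def read_settings(path, **overrides) -> FilterSettings:
    """Read FilterSettings from a flat key=value file.

    Recognises both the field names and the short filter names
    (len/supp/null/ci-len); keyword overrides (e.g. from CLI flags) win.
    Unknown keys raise.
    """
    values = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in _SETTING_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            values[_ALIASES.get(key, key)] = _SETTING_KEYS[key](raw.strip())
    values.update({k: v for k, v in overrides.items() if v is not None})
    return FilterSettings(**values)


def exome_preset() -> FilterSettings:
    """Filter settings for exome-capture data: at least 10 supporting read
    pairs; the remaining thresholds are this package's defaults (the
    faux-reference calibration is not applicable to capture data)."""
    return FilterSettings(min_inner_len=150, min_supp=10,
                          min_null_gap_pct=10.0, max_ci_len=700)


def _alu_tree(annotation: RepeatAnnotation):
    trees: dict[str, IntervalTree] = {}
    for r in annotation.alus():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    return trees


def near_alu_rule(call: AluCallRecord, alu_trees,
                  maxtsd: int = MAXTSD) -> bool:
    """Require a non-ambiguous breakpoint for calls near reference Alus.

    The call's CI extended by ``maxtsd`` defines the proximity window.  For
    each same-strand reference Alu, its head lying in the window makes the
    call's head-side breakpoint ambiguous (donor reads may map to the
    consensus rather than the diverged reference copy); likewise its tail
    makes the tail-side breakpoint ambiguous.  The call passes iff at least
    one *detected* breakpoint is non-ambiguous.  Calls away from any
    reference Alu pass unconditionally.
    """
    tree = alu_trees.get(call.chrom)
    lo, hi = call.ci_start - maxtsd, call.ci_end + maxtsd
    if tree is None:
        return True
    hits = [iv.data for iv in tree.overlap(lo, hi)]
    if not hits:
        return True
    # head side of the call in genome coordinates: start side for + calls
    head_side = "start" if call.strand == "+" else "end"
    tail_side = "end" if call.strand == "+" else "start"
    ambiguous = set()
    for alu in hits:
        if alu.strand != call.strand:
            continue
        if lo <= alu.head_pos() <= hi:
            ambiguous.add(head_side)
        if lo <= alu.tail_pos() <= hi:
            ambiguous.add(tail_side)
    detected_ok = call.breakpoints - ambiguous
    return bool(detected_ok)


def passes(call: AluCallRecord, settings: FilterSettings,
           alu_trees=None, maxtsd: int = MAXTSD) -> bool:
    if call.inner_len < settings.min_inner_len:
        return False
    if call.supp < settings.min_supp:
        return False
    if (call.score_alu - call.score_null) < \
            settings.min_null_gap_pct / 100.0 * call.score_alu:
        return False
    if call.ci_len > settings.max_ci_len:
        return False
    if alu_trees is not None and not near_alu_rule(call, alu_trees, maxtsd):
        return False
    return True


def apply_filters(calls, settings: FilterSettings,
                  repeat_annotation: RepeatAnnotation | None = None,
                  maxtsd: int = MAXTSD) -> list[AluCallRecord]:
    """Filter a call set; the near-reference-Alu rule applies whenever an
    annotation is supplied."""
    trees = _alu_tree(repeat_annotation) if repeat_annotation is not None else None
    return [c for c in calls if passes(c, settings, trees, maxtsd)]
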