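"""Exon/intron inference from CIGAR strings and skip-exon interval logic.

This is the core of the method.  A chimeric alignment's CIGAR string is
decomposed into reference-coordinate blocks: M blocks are exon evidence,
N blocks are intron evidence.  Coordinates follow the recurrence

    s_1 = POS,   s_i = e_{i-1} + 1,   e_i = s_i + n_i - 1

over the M/N elements (1-based inclusive).  CIGAR-derived exons are
snapped to the reference annotation when they intersect an annotated
exon.  A *skip exon* is any interval that is simultaneously inside the
pooled exon evidence and the pooled intron evidence of one circRNA; skip
exons are subtracted from the exon set before assembly.

All intervals are 1-based inclusive ``(start, end)`` tuples.  The merge
/ intersect / subtract primitives on such tuples live here because the
skip-exon definition *is* interval intersection and deletion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from intervaltree import IntervalTree

from .io import AnnotatedExon

Interval = tuple[int, int]

_CIGAR_ELEMENT = re.compile(r"(\d+)([A-Z=])")


@dataclass(frozen=True)
class CigarSegment:
    """One reference-consuming CIGAR block: an exon (M) or intron (N)."""

    opcode: Literal["M", "N"]
    n: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.n:
            raise ValueError(f"segment span {self.start}-{self.end} != length {self.n}")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass
class IntervalSet:
    """A typed, ordered collection of 1-based inclusive intervals on one chromosome."""

    chrom: str
    intervals: list[Interval] = field(default_factory=list)
    kind: Literal["exon", "intron", "skip"] = "exon"

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bases(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


def parse_cigar_segments(
    pos: int, cigar: str, d_advances_reference: bool = False
) -> list[CigarSegment]:
    """Decompose a CIGAR string into exon (M) and intron (N) reference blocks.

    ``pos`` is the 1-based alignment start.  S, H and I elements never
    consume reference and are skipped.  D (deletion) is skipped by
    default — the method treats it as having no effect — but with
    ``d_advances_reference=True`` it advances the reference cursor by its
    length (strict SAM semantics) without emitting a block.

    Raises ``ValueError`` on an unknown opcode or a zero-length element.
    """
    if pos < 1:
        raise ValueError(f"alignment start must be >= 1, got {pos}")
    segments: list[CigarSegment] = []
    cursor = pos
    consumed = 0
    for match in _CIGAR_ELEMENT.finditer(cigar):
        n, op = int(match.group(1)), match.group(2)
        consumed += len(match.group(0))
        if n == 0:
            raise ValueError(f"zero-length CIGAR element in {cigar!r}")
        if op in ("M", "N"):
            segments.append(CigarSegment(op, n, cursor, cursor + n - 1))
            cursor += n
        elif op == "D" and d_advances_reference:
            cursor += n
        elif op in ("S", "H", "I", "D"):
            continue
        else:
            raise ValueError(f"unsupported CIGAR opcode {op!r} in {cigar!r}")
    if consumed != len(cigar):
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return segments


# ---------------------------------------------------------------------------
# interval primitives (1-based inclusive)


def _merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Coalesce overlapping or bookended (gap 0) intervals; sort by start."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            prev_s, prev_e = merged[-1]
            merged[-1] = (prev_s, max(prev_e, end))
        else:
            merged.append((start, end))
    return merged


def _intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Maximal intervals belonging to both merged sets (linear sweep)."""
    a, b = _merge(a), _merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Interval difference a \\ b with inclusive semantics."""
    b = _merge(b)
    out: list[Interval] = []
    for start, end in _merge(a):
        cursor = start
        for bs, be in b:
            if be < cursor or bs > end:
                continue
            if bs > cursor:
                out.append((cursor, bs - 1))
            cursor = be + 1
            if cursor > end:
                break
        if cursor <= end:
            out.append((cursor, end))
    return out


def merge_intervals(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Union evidence from multiple reads into one coalesced interval set."""
    if not sets:
        raise ValueError("merge_intervals requires at least one set")
    chroms = {s.chrom for s in sets}
    kinds = {s.kind for s in sets}
    if len(chroms) > 1 or len(kinds) > 1:
        raise ValueError("all sets must share chromosome and kind")
    all_intervals = [iv for s in sets for iv in s.intervals]
    return IntervalSet(sets[0].chrom, _merge(all_intervals), sets[0].kind)


# ---------------------------------------------------------------------------
# annotation snapping


def snap_exon_to_annotation(
    exon: Interval, annotated: Sequence[AnnotatedExon]
) -> tuple[Interval, str]:
    """Replace a CIGAR-derived exon with the intersecting annotated exon.

    If at least one annotated exon intersects, the one with the largest
    overlap wins (ties broken by smaller start) and the provenance is
    ``"annotation"``; otherwise the CIGAR exon is returned unchanged
    with provenance ``"cigar"``.
    """
    start, end = exon
    best: AnnotatedExon | None = None
    best_key: tuple[int, int] | None = None
    for ann in annotated:
        overlap = min(end, ann.end) - max(start, ann.start) + 1
        if overlap <= 0:
            continue
        key = (-overlap, ann.start)
        if best_key is None or key < best_key:
            best, best_key = ann, key
    if best is None:
        return exon, "cigar"
    return (best.start, best.end), "annotation"


class AnnotationIndex:
    """Per-chromosome interval tree over annotated exons, for fast snapping."""

    def __init__(self, exons: Iterable[AnnotatedExon]):
        self._trees: dict[str, IntervalTree] = {}
        for exon in exons:
            tree = self._trees.setdefault(exon.chrom, IntervalTree())
            # tree coordinates are half-open; store end+1
            tree.addi(exon.start, exon.end + 1, exon)

    def overlapping(self, chrom: str, interval: Interval) -> list[AnnotatedExon]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(interval[0], interval[1] + 1)]

    def snap(self, chrom: str, interval: Interval) -> tuple[Interval, str]:
        return snap_exon_to_annotation(interval, self.overlapping(chrom, interval))


# ---------------------------------------------------------------------------
# skip exons


def detect_skip_exons(exons: IntervalSet, introns: IntervalSet) -> IntervalSet:
    """Intervals supported as exon by one read but spanned by an intron gap in another.

    Returns every maximal interval that lies inside both the pooled exon
    and the pooled intron evidence; a full exon or only part of one may
    come out.
    """
    if exons.chrom != introns.chrom:
        raise ValueError("exon and intron sets must share a chromosome")
    return IntervalSet(exons.chrom, _intersect(exons.intervals, introns.intervals), "skip")


def subtract_skip_exons(exons: IntervalSet, skips: IntervalSet) -> IntervalSet:
    """Delete skip-exon intervals from the exon set (inclusive difference).

    An exon fully covered by a skip disappears, a partially covered exon
    is truncated, and an internally pierced exon splits in two.
    """
    if exons.chrom != skips.chrom:
        raise ValueError("exon and skip sets must share a chromosome")
    return IntervalSet(exons.chrom, _subtract(exons.intervals, skips.intervals), "exon")
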