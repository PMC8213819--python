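"""Genomic coordinate model and interval arithmetic.

All coordinates are held internally as 0-based, half-open intervals.
Printed coordinates in the literature mix conventions (1-based fully
closed vs. end-exclusive), so parsing and formatting take an explicit
:class:`CoordinateConvention` tag rather than guessing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class CoordinateConvention(str, Enum):
    """Named coordinate conventions for printed interval strings."""

    ZERO_BASED_HALF_OPEN = "zero_based_half_open"
    ONE_BASED_FULLY_CLOSED = "one_based_fully_closed"
    ONE_BASED_END_EXCLUSIVE = "one_based_end_exclusive"


#: accepted aliases for CLI / config use
_CONVENTION_ALIASES = {
    "bed": CoordinateConvention.ZERO_BASED_HALF_OPEN,
    "zero_based_half_open": CoordinateConvention.ZERO_BASED_HALF_OPEN,
    "gff": CoordinateConvention.ONE_BASED_FULLY_CLOSED,
    "one_based_fully_closed": CoordinateConvention.ONE_BASED_FULLY_CLOSED,
    "one_based_end_exclusive": CoordinateConvention.ONE_BASED_END_EXCLUSIVE,
}


def resolve_convention(tag: "str | CoordinateConvention") -> CoordinateConvention:
    if isinstance(tag, CoordinateConvention):
        return tag
    try:
        return _CONVENTION_ALIASES[tag.lower()]
    except KeyError:
        raise ValueError(f"unknown coordinate convention: {tag!r}") from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open interval on a named sequence.

    ``start <= end`` always; ``len(iv) == end - start``.  Strand is one of
    ``'+'``, ``'-'`` or ``'.'`` (unstranded) and does not participate in
    ordering semantics beyond tie-breaking.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start > self.end:
            raise ValueError(f"start > end: {self.start} > {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len(self), overlap/len(other)); 0 if disjoint or empty."""
        inter = self.intersection(other)
        if inter is None or len(self) == 0 or len(other) == 0:
            return 0.0
        return min(len(inter) / len(self), len(inter) / len(other))


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp on the internal half-open convention."""
    return iv.end - iv.start


_COORD_RE = re.compile(
    r"^\s*(?P<chrom>[^:\s]+)\s*:\s*(?P<start>[\d,]+)\s*-\s*(?P<end>[\d,]+)\s*$"
)


def parse_interval(
    text: str, convention: "str | CoordinateConvention"
) -> GenomicInterval:
    """Parse ``"chrom: start-end"`` (thousands separators allowed).

    The printed numbers are interpreted under ``convention`` and converted
    to the internal 0-based half-open representation.
    """
    m = _COORD_RE.match(text)
    if m is None:
        raise ValueError(f"malformed coordinate string: {text!r}")
    conv = resolve_convention(convention)
    start = int(m["start"].replace(",", ""))
    end = int(m["end"].replace(",", ""))
    if conv is CoordinateConvention.ONE_BASED_FULLY_CLOSED:
        start, end = start - 1, end
    elif conv is CoordinateConvention.ONE_BASED_END_EXCLUSIVE:
        start, end = start - 1, end - 1
    if start > end:
        raise ValueError(f"start > end after conversion in {text!r}")
    return GenomicInterval(m["chrom"], start, end)


def format_interval(
    iv: GenomicInterval,
    convention: "str | CoordinateConvention",
    thousands: bool = False,
) -> str:
    """Inverse of :func:`parse_interval`: emit under the given convention."""
    conv = resolve_convention(convention)
    start, end = iv.start, iv.end
    if conv is CoordinateConvention.ONE_BASED_FULLY_CLOSED:
        start, end = start + 1, end
    elif conv is CoordinateConvention.ONE_BASED_END_EXCLUSIVE:
        start, end = start + 1, end + 1
    fmt = "{:,}" if thousands else "{}"
    return f"{iv.chrom}: {fmt.format(start)}-{fmt.format(end)}"


# ---------------------------------------------------------------------------
# interval set arithmetic (all functions expect a single chromosome per call
# unless noted; intervals need not be sorted on input)
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, non-overlapping list.

    Abutting intervals (sharing a boundary base) are merged; all inputs must
    be on one chromosome.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def complement_within(
    bounds: GenomicInterval, intervals: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of ``bounds`` not covered by any interval; sorted, non-overlapping."""
    merged = [
        iv
        for iv in merge_intervals(intervals)
        if iv.chrom == bounds.chrom and iv.overlaps(bounds)
    ]
    out: list[GenomicInterval] = []
    cursor = bounds.start
    for iv in merged:
        lo = max(iv.start, bounds.start)
        if lo > cursor:
            out.append(GenomicInterval(bounds.chrom, cursor, lo))
        cursor = max(cursor, min(iv.end, bounds.end))
    if cursor < bounds.end:
        out.append(GenomicInterval(bounds.chrom, cursor, bounds.end))
    return out


def subtract_intervals(
    regions: Sequence[GenomicInterval], mask: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Remove masked bases from each region (half-open semantics)."""
    masked = merge_intervals(mask)
    out: list[GenomicInterval] = []
    for region in sorted(regions, key=lambda iv: (iv.chrom, iv.start, iv.end)):
        cursor = region.start
        for m in masked:
            if m.chrom != region.chrom or m.end <= region.start:
                continue
            if m.start >= region.end:
                break
            if m.start > cursor:
                out.append(GenomicInterval(region.chrom, cursor, m.start))
            cursor = max(cursor, m.end)
        if cursor < region.end:
            out.append(GenomicInterval(region.chrom, cursor, region.end))
    return out


def intersect_interval_lists(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise intersections of two merged interval lists, sorted."""
    out = []
    for iv in a:
        for jv in b:
            inter = iv.intersection(jv)
            if inter is not None and len(inter) > 0:
                out.append(inter)
    return merge_intervals(out)


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# annotations and masks
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene (or pseudogene fragment) with a transcript span and exons."""

    gene_id: str
    biotype: str  # e.g. "protein_coding", "pseudogene"
    transcript: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ex in self.exons:
            if not self.transcript.contains(ex):
                raise ValueError(
                    f"exon {ex} outside transcript {self.transcript} "
                    f"of gene {self.gene_id}"
                )


@dataclass
class AnnotationSet:
    """Gene models plus file provenance; the intergenic complement is
    computed against whole transcript footprints (pseudogene fragments
    included), so UTRs and introns count as genic."""

    genes: list[GeneModel]
    source: str = "memory"

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.transcript.chrom, g.transcript.start))

    def footprints(self, chrom: "str | None" = None) -> list[GenomicInterval]:
        ivs = [
            g.transcript
            for g in self.genes
            if chrom is None or g.transcript.chrom == chrom
        ]
        return merge_intervals(ivs)

    def chromosomes(self) -> list[str]:
        return sorted({g.transcript.chrom for g in self.genes})


@dataclass
class MaskTrack:
    """Repeat / masked intervals; normalized to merged form per chromosome."""

    intervals: list[GenomicInterval]
    source: str = "memory"

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        merged: list[GenomicInterval] = []
        for chrom in sorted(by_chrom):
            merged.extend(merge_intervals(by_chrom[chrom]))
        self.intervals = merged

    def on(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]


def intergenic_regions(
    ann: AnnotationSet, bounds: GenomicInterval
) -> list[GenomicInterval]:
    """Complement of all gene/pseudogene footprints within ``bounds``."""
    chroms = ann.chromosomes()
    if chroms and bounds.chrom not in chroms:
        raise ValueError(
            f"bounds chromosome {bounds.chrom!r} absent from annotation "
            f"(has {chroms})"
        )
    return complement_within(bounds, ann.footprints(bounds.chrom))


def subtract_mask(
    regions: Sequence[GenomicInterval], mask: MaskTrack
) -> list[GenomicInterval]:
    """Remove repeat-masked bases from candidate search regions."""
    return subtract_intervals(regions, mask.intervals)
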