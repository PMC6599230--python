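"""Genomic interval algebra.

All coordinates are 0-based, half-open ``[start, end)``; the width of an
interval is ``end - start``.  This is the convention under which every DMR
location printed in the published result tables reproduces its printed
width exactly, and it matches BED.

Location strings such as ``chr10:1281019-1,282,852`` (en-dash or hyphen,
optional digit-group commas) are accepted on input; the canonical rendering
is plain ``chrN:start-end``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "parse_location",
    "merge",
    "subtract",
    "overlaps",
]

_LOCATION_RE = re.compile(
    r"^(?P<chrom>[\w.]+):(?P<start>\d[\d,]*)\s*[–—-]\s*(?P<end>\d[\d,]*)$"
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval on unnamed chromosome")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class LocationParseError(ValueError):
    """A location string did not match ``chrN:start-end``."""


def parse_location(text: str) -> GenomicInterval:
    """Parse ``chrN:start-end`` (commas and en-dashes tolerated).

    >>> parse_location("chr10:1281019–1,282,852")
    GenomicInterval(chrom='chr10', start=1281019, end=1282852)
    """
    m = _LOCATION_RE.match(text.strip())
    if m is None:
        raise LocationParseError(f"malformed location string: {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    try:
        return GenomicInterval(m.group("chrom"), start, end)
    except ValueError as exc:
        raise LocationParseError(f"invalid location {text!r}: {exc}") from exc


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp.

    Book-ended intervals (``a.end == b.start``) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge(intervals: Iterable[GenomicInterval]) -> "PeakSet":
    """Minimal sorted disjoint cover of the union.

    Book-ended intervals are coalesced, so the result never contains two
    intervals that touch.
    """
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return PeakSet(out, validate=False)


def subtract(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]) -> "PeakSet":
    """Set difference a \\ b as a merged PeakSet."""
    a_m = merge(a)
    b_m = merge(b)
    out: list[GenomicInterval] = []
    for iv in a_m:
        cursor = iv.start
        for cut in b_m.overlapping(iv):
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return PeakSet(out, validate=False)


@dataclass
class PeakSet:
    """An ordered, duplicate-free collection of intervals (e.g. peak calls).

    Intervals are kept sorted by (chrom, start, end).  ``source_label``
    identifies the sample/replicate the peaks came from.
    """

    intervals: Sequence[GenomicInterval] = field(default_factory=list)
    source_label: str = ""
    validate: bool = True

    def __post_init__(self) -> None:
        ivs = list(self.intervals)
        if self.validate:
            ivs = sorted(set(ivs))
        self.intervals = ivs
        del self.validate

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if isinstance(other, PeakSet):
            return self.intervals == other.intervals
        return NotImplemented

    @property
    def total_length(self) -> int:
        return sum(iv.width for iv in merge(self.intervals))

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals overlapping ``query`` (linear scan per chrom)."""
        import bisect

        ivs = self.intervals
        # first interval whose (chrom, start) could still overlap
        lo = bisect.bisect_left(ivs, (query.chrom, 0, 0), key=lambda v: (v.chrom, v.start, v.end))
        out = []
        for iv in ivs[lo:]:
            if iv.chrom != query.chrom or iv.start >= query.end:
                break
            if overlaps(iv, query):
                out.append(iv)
        return out

    def any_overlap(self, query: GenomicInterval) -> bool:
        return bool(self.overlapping(query))
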