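"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open ([start, end)).
Conversion from the 1-based inclusive convention used by GTF files and
``chrom:start-end`` region strings happens at the I/O boundary only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval with an optional strand.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, start: int, end: int) -> bool:
        """True if [start, end) lies entirely inside this interval."""
        return self.start <= start and end <= self.end

    def __str__(self) -> str:  # 0-based half-open, for logs and table keys
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or adjacent intervals into a minimal sorted disjoint set.

    All intervals must share chrom and strand (a mix raises ``ValueError``);
    adjacency (end == next start) is merged because the base sets are contiguous.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    strands = {iv.strand for iv in ivs}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("cannot merge intervals across chromosomes or strands")
    merged: list[GenomicInterval] = []
    cur_start, cur_end = ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end, ivs[0].strand))
            cur_start, cur_end = iv.start, iv.end
    merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end, ivs[0].strand))
    return merged


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


_REGION_RE = re.compile(r"^([^:]+):([0-9,]+)-([0-9,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``chrom:start-end`` region string.

    Returns the corresponding 0-based half-open interval, e.g.
    ``chr11:2103768-2222439`` -> GenomicInterval('chr11', 2103767, 2222439).
    """
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
    chrom = m.group(1)
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    if start1 < 1 or end1 < start1:
        raise ValueError(f"invalid 1-based region {text!r}")
    return GenomicInterval(chrom, start1 - 1, end1)


def format_region(iv: GenomicInterval) -> str:
    """Render an interval as a 1-based inclusive region string."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"
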