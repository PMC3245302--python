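"""Genomic interval arithmetic in the 1-based inclusive convention.

All coordinates handled by this package are 1-based and inclusive (the
convention used in reports and figures); BED-family files on disk use the
standard 0-based half-open convention, and conversion happens exactly once,
in :func:`to_bed_fields` / :func:`from_bed_fields`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive span on a single sequence."""

    start: int
    end: int
    chrom: str = "chr20"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        """Number of bases covered: end - start + 1."""
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


def gap(left: GenomicInterval, right: GenomicInterval) -> int:
    """Bases strictly between two ordered intervals: right.start - left.end - 1."""
    if right.start <= left.end:
        raise ValueError("intervals overlap or are unordered")
    return right.start - left.end - 1


def to_kb(bp: int) -> int:
    """Nearest-integer kilobases, rounding half up (482,727 bp -> 483 kb)."""
    return math.floor(bp / 1000 + 0.5)


def to_bed_fields(iv: GenomicInterval) -> tuple[str, int, int]:
    """1-based inclusive -> 0-based half-open (chrom, chromStart, chromEnd)."""
    return iv.chrom, iv.start - 1, iv.end


def from_bed_fields(chrom: str, bed_start: int, bed_end: int) -> GenomicInterval:
    """0-based half-open BED fields -> 1-based inclusive interval."""
    return GenomicInterval(bed_start + 1, bed_end, chrom)
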