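"""Genomic intervals and coordinate-convention handling.

All coordinates are 0-based half-open internally.  Files and human-readable
reports that follow the 1-based inclusive convention (the style genome
browsers print, e.g. ``chr11:25,566,599-28,305,611``) are converted on the
way in and out; the round trip is lossless.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "from_one_based",
    "to_one_based",
    "parse_region",
    "overlap_length",
    "reciprocal_overlap",
    "merge_intervals",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    source_convention: str = field(default="zero_half_open", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and overlap_length(
            (self.start, self.end), (other.start, other.end)
        ) > 0

    def as_one_based(self) -> tuple[str, int, int]:
        """Return (chrom, start, end) in 1-based inclusive coordinates."""
        return self.chrom, self.start + 1, self.end

    def __str__(self) -> str:
        chrom, s, e = self.as_one_based()
        return f"{chrom}:{s:,}-{e:,}"


def from_one_based(chrom: str, start: int, end: int) -> GenomicInterval:
    """Build an interval from 1-based inclusive coordinates."""
    return GenomicInterval(chrom, start - 1, end, source_convention="one_inclusive")


def to_one_based(iv: GenomicInterval) -> tuple[str, int, int]:
    return iv.as_one_based()


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a browser-style region string (1-based inclusive), e.g.
    ``chr11:28,227,839-28,227,938``."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    return from_one_based(chrom, start, end)


def overlap_length(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """min(overlap/len_a, overlap/len_b) — the identity criterion used when
    clustering domains into epialleles."""
    ov = overlap_length(a, b)
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
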