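"""Genomic-interval primitives and interval arithmetic.

Coordinates are 1-based and inclusive throughout the package (the
convention used for array CNV reporting); BED input/output converts at
the boundary (see :mod:`cnvburden.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "interval_length_kb",
    "shared_bases",
    "reciprocal_overlap",
    "merge_intervals",
    "fraction_covered",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome label (``"chr4"`` style; any non-empty string accepted).
    start, end : int
        First and last base of the interval, 1-based inclusive.
        ``end >= start >= 1`` is enforced.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start}) on {self.chrom}"
            )

    @property
    def length_bp(self) -> int:
        """Number of bases spanned (inclusive of both endpoints)."""
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:  # chr4:43,276-146,490 display style
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


def interval_length_kb(interval: GenomicInterval) -> float:
    """Interval length in kb, rounded half-up to one decimal.

    Rounding is a presentation choice only; internal computation always
    uses full-precision base-pair lengths.
    """
    kb = Decimal(interval.length_bp) / Decimal(1000)
    return float(kb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def shared_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases in the intersection of two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0, hi - lo + 1)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap fraction: shared bases / length of the larger interval.

    Symmetric in its arguments; 0 for different chromosomes or disjoint
    intervals; 1 only when the two intervals are identical.
    """
    shared = shared_bases(a, b)
    if shared == 0:
        return 0.0
    return shared / max(a.length_bp, b.length_bp)


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> List[GenomicInterval]:
    """Merge overlapping or book-ended intervals into a disjoint union."""
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + 1:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def fraction_covered(
    a: GenomicInterval, track_intervals: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``a``'s bases covered by the union of ``track_intervals``.

    Track intervals are merged first so stacked intervals are not double
    counted. Returns a value in [0, 1].
    """
    covered = 0
    for iv in merge_intervals(track_intervals):
        covered += shared_bases(a, iv)
    return covered / a.length_bp
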