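"""Genomic intervals and the primitive operations the pipeline builds on.

All coordinates are 0-based half-open, BED-style. An :class:`OCRSet` is the
unit of chromatin accessibility: a sorted, non-overlapping collection of open
chromatin regions (OCRs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .exceptions import InputError

__all__ = [
    "GenomicInterval",
    "OCRSet",
    "FragmentSet",
    "merge_intervals",
    "intervals_overlap",
    "total_bp",
    "intersection_bp",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval with 0-based inclusive start and exclusive end."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise InputError("interval chromosome must be non-empty")
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base pair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping intervals into maximal non-overlapping intervals.

    Output is sorted by (chrom, start). Bookended intervals (sharing only an
    endpoint, e.g. [0,10) and [10,20)) are merged, matching bedtools-merge
    semantics.
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        ivs = sorted(_by_chrom(intervals)[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Base pairs covered by the union of the intervals."""
    return sum(len(iv) for iv in merge_intervals(intervals)) if intervals else 0


def intersection_bp(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Base pairs in the intersection of the unions of two interval sets."""
    a_m = merge_intervals(list(a)) if a else []
    b_m = merge_intervals(list(b)) if b else []
    b_chrom = _by_chrom(b_m)
    bp = 0
    for iv in a_m:
        for jv in b_chrom.get(iv.chrom, ()):
            lo = max(iv.start, jv.start)
            hi = min(iv.end, jv.end)
            if lo < hi:
                bp += hi - lo
    return bp


@dataclass
class OCRSet:
    """Sorted, pairwise non-overlapping open chromatin regions.

    Built by :func:`ocrcell.io.build_consensus`; ``ids`` name each OCR and
    index the rows of count matrices downstream.
    """

    intervals: list[GenomicInterval]
    label: str = "consensus"

    def __post_init__(self):
        key = [(iv.chrom, iv.start) for iv in self.intervals]
        if key != sorted(key):
            raise InputError("OCRSet intervals must be sorted by (chrom, start)")
        prev: GenomicInterval | None = None
        for iv in self.intervals:
            if prev is not None and intervals_overlap(prev, iv):
                raise InputError(
                    f"OCRSet intervals overlap: {prev} and {iv}"
                )
            prev = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def ids(self) -> list[str]:
        return [
            iv.name if iv.name else f"{iv.chrom}:{iv.start}-{iv.end}"
            for iv in self.intervals
        ]

    def arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, row index) arrays for fast overlap."""
        out: dict[str, tuple[list, list, list]] = {}
        for i, iv in enumerate(self.intervals):
            starts, ends, idx = out.setdefault(iv.chrom, ([], [], []))
            starts.append(iv.start)
            ends.append(iv.end)
            idx.append(i)
        return {
            c: (np.asarray(s), np.asarray(e), np.asarray(i))
            for c, (s, e, i) in out.items()
        }

    def overlapping_indices(self, iv: GenomicInterval) -> np.ndarray:
        """Row indices of OCRs sharing >=1 bp with ``iv`` (sorted OCRs)."""
        arrays = self.arrays()
        if iv.chrom not in arrays:
            return np.empty(0, dtype=int)
        starts, ends, idx = arrays[iv.chrom]
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        return idx[lo:hi]


@dataclass
class FragmentSet:
    """Per-sample ATAC-seq fragments; duplicates permitted (pre-dedup)."""

    sample_id: str
    fragments: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)
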