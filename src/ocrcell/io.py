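"""Reading/writing standard formats, consensus OCR construction, fragment
counting and the QC metrics the downstream model consumes (FRiP, PBC, TSS
enrichment).

BED is read and written tab-separated without header, coordinates 0-based
half-open. Count matrices are TSV with OCR ids as the index column and
sample ids as the header row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError, ParseError, UndefinedMetricError
from .intervals import (
    FragmentSet,
    GenomicInterval,
    OCRSet,
    merge_intervals,
)

__all__ = [
    "read_bed",
    "write_bed",
    "build_consensus",
    "count_fragments",
    "frip",
    "pbc",
    "tss_enrichment",
    "QCMetrics",
    "read_counts_tsv",
    "write_counts_tsv",
]


def read_bed(path) -> list[GenomicInterval]:
    """Parse a BED3/BED4/BED6 file into intervals.

    Raises :class:`ParseError` with the offending line number on malformed
    coordinates (negative, non-integer, or start >= end).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >=3 tab-separated columns", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", lineno) from exc
            if start < 0 or start >= end:
                raise ParseError(
                    f"invalid interval {chrom}:{start}-{end}", lineno
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED; column count follows the populated fields."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                cols.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand is not None:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def build_consensus(
    peak_sets: Sequence[Iterable[GenomicInterval]],
    blacklist: Iterable[GenomicInterval] = (),
    label: str = "consensus",
) -> OCRSet:
    """Union all peak sets into maximal non-overlapping consensus OCRs.

    A peak is retained if called in one or more input sets (plain union);
    overlapping peaks are merged, and any merged interval sharing >=1 bp with
    a blacklisted region is removed entirely (not trimmed).
    """
    all_peaks = [iv for peaks in peak_sets for iv in peaks]
    merged = merge_intervals(all_peaks) if all_peaks else []
    blacklist = list(blacklist)
    if blacklist:
        bl_merged = merge_intervals(blacklist)
        bl_by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in bl_merged:
            bl_by_chrom.setdefault(iv.chrom, []).append(iv)
        kept = []
        for iv in merged:
            hits = bl_by_chrom.get(iv.chrom, ())
            if any(iv.start < b.end and b.start < iv.end for b in hits):
                continue
            kept.append(iv)
        merged = kept
    named = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"{iv.chrom}:{iv.start}-{iv.end}")
        for iv in merged
    ]
    return OCRSet(named, label=label)


def _overlap_bounds(
    ocrs: OCRSet, fragments: Iterable[GenomicInterval]
) -> tuple[np.ndarray, np.ndarray]:
    """For each fragment, the [lo, hi) slice of overlapped OCR rows.

    Relies on the consensus OCRs being sorted and non-overlapping: the OCRs a
    fragment [s, e) overlaps are exactly those with end > s and start < e,
    which form a contiguous run in sorted order.
    """
    arrays = ocrs.arrays()
    lo_all, hi_all = [], []
    for frag in fragments:
        if frag.chrom not in arrays:
            lo_all.append(0)
            hi_all.append(0)
            continue
        starts, ends, idx = arrays[frag.chrom]
        lo = np.searchsorted(ends, frag.start, side="right")
        hi = np.searchsorted(starts, frag.end, side="left")
        base = idx[0] if len(idx) else 0
        lo_all.append(base + lo)
        hi_all.append(base + hi)
    return np.asarray(lo_all, dtype=int), np.asarray(hi_all, dtype=int)


def count_fragments(fragments: FragmentSet, ocrs: OCRSet) -> np.ndarray:
    """Per-OCR fragment counts: a fragment adds 1 to every OCR it overlaps
    by >=1 bp (at most once per OCR since consensus OCRs are disjoint)."""
    counts = np.zeros(len(ocrs), dtype=np.int64)
    if len(fragments) == 0 or len(ocrs) == 0:
        return counts
    lo, hi = _overlap_bounds(ocrs, fragments.fragments)
    # difference-array trick: +1 at lo, -1 at hi, cumulative sum
    delta = np.zeros(len(ocrs) + 1, dtype=np.int64)
    np.add.at(delta, lo, 1)
    np.add.at(delta, hi, -1)
    counts = np.cumsum(delta[:-1])
    return counts


def frip(fragments: FragmentSet, ocrs: OCRSet) -> float:
    """Fraction of fragments overlapping at least one OCR."""
    n = len(fragments)
    if n == 0:
        raise UndefinedMetricError(
            f"FRiP undefined for sample {fragments.sample_id}: zero fragments"
        )
    if len(ocrs) == 0:
        return 0.0
    lo, hi = _overlap_bounds(ocrs, fragments.fragments)
    return float(np.count_nonzero(hi > lo) / n)


def pbc(read_positions: Sequence[tuple[str, int, str]]) -> float:
    """PCR bottleneck coefficient: distinct (chrom, start, strand) positions
    divided by the number of reads."""
    if len(read_positions) == 0:
        raise UndefinedMetricError("PBC undefined: zero reads")
    return len(set(read_positions)) / len(read_positions)


def tss_enrichment(
    fragments: FragmentSet,
    tss: Sequence[int] | Sequence[tuple[str, int]],
    flank: int = 1000,
    edge: int = 100,
) -> float:
    """TSS read enrichment from fragments within ``flank`` bp of a TSS.

    Per-bp fragment coverage is aggregated over all windows
    [TSS - flank, TSS + flank); the score is the coverage at the TSS
    position divided by the mean coverage of the outermost ``edge`` bp on
    each side of the window. Returns 0 when no fragment touches any window.
    If the flank baseline is zero but the window is not empty, the baseline
    falls back to the window-wide mean per-bp coverage.

    ``tss`` entries are either bare positions (single-chromosome input) or
    (chrom, position) pairs.
    """
    if len(tss) == 0:
        raise InputError("need at least one TSS")
    width = 2 * flank
    pileup = np.zeros(width, dtype=np.float64)
    norm_tss: list[tuple[str | None, int]] = [
        t if isinstance(t, tuple) else (None, int(t)) for t in tss
    ]
    for chrom, pos in norm_tss:
        win_start = pos - flank
        for frag in fragments.fragments:
            if chrom is not None and frag.chrom != chrom:
                continue
            lo = max(frag.start, win_start) - win_start
            hi = min(frag.end, win_start + width) - win_start
            if lo < hi:
                pileup[lo:hi] += 1.0
    if pileup.sum() == 0:
        return 0.0
    baseline = 0.5 * (pileup[:edge].mean() + pileup[-edge:].mean())
    if baseline == 0:
        baseline = pileup.mean()
    return float(pileup[flank] / baseline)


@dataclass
class QCMetrics:
    """Per-sample quality metrics feeding the covariate model."""

    frip: float
    pbc: float
    tss_enrichment: float
    total_fragments: int

    def __post_init__(self):
        if not (0.0 <= self.frip <= 1.0):
            raise InputError(f"FRiP must be in [0,1], got {self.frip}")
        if not (0.0 <= self.pbc <= 1.0):
            raise InputError(f"PBC must be in [0,1], got {self.pbc}")
        if self.tss_enrichment < 0:
            raise InputError("TSS enrichment must be >= 0")


def read_counts_tsv(path) -> pd.DataFrame:
    """OCR x sample count matrix from TSV (index = OCR ids, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise InputError("count matrix contains negative entries")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")
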