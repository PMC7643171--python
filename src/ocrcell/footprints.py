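"""Transcription-factor footprint burden and motif enrichment.

Footprinted binding sites carry a binding probability. Per motif,
overlapping same-motif sites (e.g. palindromic calls on opposite strands)
are deduplicated keeping the highest-probability site. Because many factors
share near-identical motifs, a non-redundant motif set is derived by
iteratively removing motifs whose sites coincide positionally with another
motif's sites. The gene-level regulatory burden sums, over the surviving
sites, p_bind * exp(-d / decay_scale) where d is the bp distance from the
site midpoint to the gene's nearest TSS (zero beyond 10 decay scales).
Group differences are aggregated as mean centered ranks of burden
differences over all cross-group sample pairs. Motif overrepresentation in
cell-specific OCRs is a one-sided binomial test with the success probability
set by bp coverage of the target OCRs (coverage-aware).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .intervals import GenomicInterval, OCRSet, merge_intervals, total_bp

__all__ = [
    "BindingSite",
    "RegulatoryBurden",
    "dedupe_sites",
    "prune_motifs",
    "site_gene_weight",
    "burden_matrix",
    "rank_aggregate",
    "motif_enrichment",
]


@dataclass(frozen=True)
class BindingSite:
    """A footprinted motif occurrence with its binding probability."""

    motif_id: str
    interval: GenomicInterval
    p_bind: float
    group: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_bind <= 1.0):
            raise InputError(f"p_bind must be in [0,1], got {self.p_bind}")


@dataclass
class RegulatoryBurden:
    """Gene x sample-group burden scores over a non-redundant motif set."""

    scores: pd.DataFrame
    decay_scale: float
    motif_set: frozenset[str]

    def __post_init__(self):
        if (self.scores.values < 0).any():
            raise InputError("burden scores must be nonnegative")


def dedupe_sites(sites: Sequence[BindingSite]) -> list[BindingSite]:
    """Remove overlapping same-motif sites, keeping the most probable.

    Greedy by descending p_bind (ties broken by leftmost start): a site is
    kept iff it does not overlap an already-kept site of the same motif.
    Call per motif (and per sample group when sites are group-resolved).
    """
    order = sorted(
        sites, key=lambda s: (-s.p_bind, s.interval.chrom, s.interval.start, s.interval.end)
    )
    kept: list[BindingSite] = []
    for s in order:
        clash = any(
            k.motif_id == s.motif_id
            and k.group == s.group
            and k.interval.chrom == s.interval.chrom
            and k.interval.start < s.interval.end
            and s.interval.start < k.interval.end
            for k in kept
        )
        if not clash:
            kept.append(s)
    kept.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    return kept


def _site_match_share(a: list[BindingSite], b: list[BindingSite], min_overlap: float) -> float:
    """Fraction of a's sites overlapped >= min_overlap of the shorter site's
    length by some site of b."""
    if not a:
        return 0.0
    hit = 0
    for sa in a:
        for sb in b:
            if sa.interval.chrom != sb.interval.chrom:
                continue
            ov = min(sa.interval.end, sb.interval.end) - max(sa.interval.start, sb.interval.start)
            if ov >= min_overlap * min(len(sa.interval), len(sb.interval)):
                hit += 1
                break
    return hit / len(a)


def prune_motifs(
    sites_by_motif: dict[str, Sequence[BindingSite]],
    site_share: float = 0.5,
    positional_overlap: float = 0.5,
) -> set[str]:
    """Iteratively reduce motifs to a non-redundant set.

    A pair of motifs is redundant when at least ``site_share`` of the
    smaller motif's sites each overlap a site of the other motif by at
    least ``positional_overlap`` of the shorter site's length. While any
    redundant pair remains, the most redundant pair is resolved by removing
    the motif with fewer sites (ties by lexicographically larger id).
    """
    if not sites_by_motif:
        raise InputError("need at least one motif")
    alive = {m: list(s) for m, s in sites_by_motif.items()}

    def redundancy(m1: str, m2: str) -> float:
        a, b = alive[m1], alive[m2]
        smaller, other = (a, b) if len(a) <= len(b) else (b, a)
        return _site_match_share(smaller, other, positional_overlap)

    while True:
        motifs = sorted(alive)
        worst, worst_pair = 0.0, None
        for i, m1 in enumerate(motifs):
            for m2 in motifs[i + 1:]:
                r = redundancy(m1, m2)
                if r >= site_share and r > worst:
                    worst, worst_pair = r, (m1, m2)
        if worst_pair is None:
            return set(alive)
        m1, m2 = worst_pair
        if len(alive[m1]) != len(alive[m2]):
            drop = m1 if len(alive[m1]) < len(alive[m2]) else m2
        else:
            drop = max(m1, m2)
        del alive[drop]


def site_gene_weight(
    site: BindingSite,
    tss_positions: Sequence[int],
    decay_scale: float,
) -> float:
    """Regulatory weight of a site on a gene: p_bind * exp(-d/decay_scale),
    d = distance from the site midpoint to the gene's nearest TSS, clipped
    to zero beyond 10 decay scales."""
    if decay_scale <= 0:
        raise InputError("decay_scale must be positive")
    if not tss_positions:
        return 0.0
    d = min(abs(site.interval.midpoint - t) for t in tss_positions)
    if d > 10.0 * decay_scale:
        return 0.0
    return site.p_bind * float(np.exp(-d / decay_scale))


def burden_matrix(
    sites: Sequence[BindingSite],
    gene_tss: dict[str, Sequence[int]],
    decay_scale: float = 10_000.0,
    motif_set: Iterable[str] | None = None,
) -> RegulatoryBurden:
    """Gene x group regulatory burden over a non-redundant motif set.

    ``gene_tss`` maps gene id -> TSS positions (same coordinate system as
    the sites). If ``motif_set`` is not given it is derived by
    :func:`prune_motifs` over all sites grouped by motif.
    """
    if motif_set is None:
        by_motif: dict[str, list[BindingSite]] = {}
        for s in sites:
            by_motif.setdefault(s.motif_id, []).append(s)
        motif_set = prune_motifs(by_motif)
    motif_set = frozenset(motif_set)
    groups = sorted({s.group for s in sites})
    genes = sorted(gene_tss)
    scores = pd.DataFrame(0.0, index=genes, columns=groups)
    for s in sites:
        if s.motif_id not in motif_set:
            continue
        for g in genes:
            w = site_gene_weight(s, gene_tss[g], decay_scale)
            if w > 0:
                scores.loc[g, s.group] += w
    return RegulatoryBurden(scores=scores, decay_scale=decay_scale, motif_set=motif_set)


def rank_aggregate(
    burden: RegulatoryBurden,
    side_a: Sequence[str],
    side_b: Sequence[str],
) -> pd.Series:
    """Mean centered rank of per-gene burden differences over group pairs.

    For each pair (a in side_a, b in side_b), genes are ranked by
    burden(a) - burden(b) and assigned centered ranks -(n-1)/2 ... (n-1)/2
    (average ranks on ties, so each pair's ranks sum to 0); the final score
    is the mean over all pairs.
    """
    if not side_a or not side_b:
        raise InputError("both sides of the comparison must be non-empty")
    n = burden.scores.shape[0]
    if n < 2:
        raise InputError("need at least 2 genes to rank")
    acc = np.zeros(n)
    n_pairs = 0
    for a in side_a:
        for b in side_b:
            diff = burden.scores[a].values - burden.scores[b].values
            acc += stats.rankdata(diff, method="average") - (n + 1) / 2.0
            n_pairs += 1
    return pd.Series(acc / n_pairs, index=burden.scores.index, name="rank_score")


def motif_enrichment(
    sites: Sequence[BindingSite],
    target_ocrs: OCRSet,
    background_ocrs: OCRSet,
    p_bind_threshold: float = 0.9,
) -> pd.DataFrame:
    """Coverage-aware binomial enrichment of bound motifs in target OCRs.

    Only sites with p_bind >= threshold ("bound") are considered. Per
    motif: n = bound sites overlapping target or background OCRs, k = those
    overlapping the target, pi = bp(target) / (bp(target) + bp(background));
    fold = (k/n)/pi and p = P(X >= k), X ~ Binomial(n, pi), Bonferroni-
    adjusted over the motifs tested. Motifs with n = 0 are flagged and
    excluded from the Bonferroni factor.
    """
    t_union = merge_intervals(list(target_ocrs))
    b_union = merge_intervals(list(background_ocrs))
    if not b_union:
        raise InputError("background OCR set is empty")
    if not t_union:
        raise InputError("target OCR set is empty")
    from .intervals import intersection_bp

    if intersection_bp(t_union, b_union) > 0:
        raise InputError("target and background OCR sets must be disjoint")
    bp_t, bp_b = total_bp(t_union), total_bp(b_union)
    pi = bp_t / (bp_t + bp_b)

    def overlaps_any(iv: GenomicInterval, union: list[GenomicInterval]) -> bool:
        return any(
            iv.chrom == u.chrom and iv.start < u.end and u.start < iv.end for u in union
        )

    per_motif: dict[str, list[int]] = {}
    for s in sites:
        if s.p_bind < p_bind_threshold:
            continue
        in_t = overlaps_any(s.interval, t_union)
        in_b = overlaps_any(s.interval, b_union)
        if not (in_t or in_b):
            continue
        n_k = per_motif.setdefault(s.motif_id, [0, 0])
        n_k[0] += 1
        if in_t:
            n_k[1] += 1
    motifs = sorted({s.motif_id for s in sites})
    tested = [m for m in motifs if m in per_motif]
    rows = []
    for m in motifs:
        if m not in per_motif:
            rows.append({"motif_id": m, "n": 0, "k": 0, "fold": np.nan,
                         "p": np.nan, "p_bonferroni": np.nan, "skipped": True})
            continue
        n, k = per_motif[m]
        fold = (k / n) / pi
        p = float(stats.binom.sf(k - 1, n, pi))
        rows.append({"motif_id": m, "n": n, "k": k, "fold": fold, "p": p,
                     "p_bonferroni": min(1.0, p * len(tested)), "skipped": False})
    return pd.DataFrame(rows).set_index("motif_id")
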