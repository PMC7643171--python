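"""Genomic-context annotation, base-pair overlap statistics, regulatory-
domain gene-set enrichment, TSS direct mapping, and variant enrichment.

Enrichment of a gene set compares OCR density in the union of the set's
regulatory domains against density in the union of all domains, with a
one-sided binomial tail on the bp-coverage fraction. Variant (eQTL
credible-set) enrichment is a 2x2 Fisher exact test of in-OCR status vs
credible status, optionally backed by a permutation null that repositions
each OCR uniformly on its own chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .intervals import (
    GenomicInterval,
    OCRSet,
    intersection_bp,
    merge_intervals,
    total_bp,
)

__all__ = [
    "GeneAnnotation",
    "RegulatoryDomain",
    "annotate_context",
    "jaccard_bp",
    "regulatory_domains",
    "great_enrichment",
    "tss_direct_map",
    "eqtl_enrichment",
]

CONTEXT_PRIORITY = ("promoter", "5utr", "3utr", "exon", "intron", "distal_intergenic")


@dataclass
class GeneAnnotation:
    """Gene model: one row per gene plus TSS and optional feature tables.

    ``genes``: gene_id, gene_name, biotype, chrom, strand (+ optional
    conserved flag / lincRNA_category). ``tss``: gene_id, chrom, pos.
    ``features`` (optional): gene_id, kind in {5utr, 3utr, exon, body},
    chrom, start, end. Duplicate gene names are disambiguated with
    "_v1", "_v2", ... suffixes at construction.
    """

    genes: pd.DataFrame
    tss: pd.DataFrame
    features: pd.DataFrame | None = None

    def __post_init__(self):
        missing = set(self.tss["gene_id"]) - set(self.genes["gene_id"])
        if missing:
            raise InputError(f"TSS reference unknown genes: {sorted(missing)[:5]}")
        without_tss = set(self.genes["gene_id"]) - set(self.tss["gene_id"])
        if without_tss:
            raise InputError(
                f"every gene needs >=1 TSS; missing for {sorted(without_tss)[:5]}"
            )
        self.genes = self.genes.copy()
        dup = self.genes["gene_name"].duplicated(keep=False)
        if dup.any():
            counters: dict[str, int] = {}
            names = self.genes["gene_name"].tolist()
            for i, nm in enumerate(names):
                if dup.iloc[i]:
                    counters[nm] = counters.get(nm, 0) + 1
                    names[i] = f"{nm}_v{counters[nm]}"
            self.genes["gene_name"] = names


@dataclass
class RegulatoryDomain:
    """A gene's presumed regulatory domain (basal window plus extension)."""

    gene_id: str
    interval: GenomicInterval
    basal: GenomicInterval

    def __post_init__(self):
        if not (
            self.interval.chrom == self.basal.chrom
            and self.interval.start <= self.basal.start
            and self.interval.end >= self.basal.end
        ):
            raise InputError("regulatory domain must contain the basal window")


def annotate_context(
    ocrs: OCRSet,
    annotation: GeneAnnotation,
    promoter_window: int = 3000,
) -> pd.Series:
    """Single genomic-context label per OCR.

    Priority: promoter (within +/- ``promoter_window`` of any TSS) >
    5'-UTR > 3'-UTR > exon > intron (in a gene body but not exonic) >
    distal intergenic. With a TSS-only annotation (no feature table), only
    promoter/distal are assigned.
    """
    labels = np.array(["distal_intergenic"] * len(ocrs), dtype=object)
    prio = {lab: i for i, lab in enumerate(CONTEXT_PRIORITY)}

    def assign(idx: np.ndarray, lab: str):
        for i in idx:
            if prio[lab] < prio[labels[i]]:
                labels[i] = lab

    feats = annotation.features
    if feats is not None:
        kind_order = [("body", "intron"), ("exon", "exon"), ("3utr", "3utr"), ("5utr", "5utr")]
        for kind, lab in kind_order:
            for _, row in feats.loc[feats["kind"] == kind].iterrows():
                iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
                assign(ocrs.overlapping_indices(iv), lab)
    for _, row in annotation.tss.iterrows():
        pos = int(row["pos"])
        win = GenomicInterval(row["chrom"], max(0, pos - promoter_window), pos + promoter_window + 1)
        assign(ocrs.overlapping_indices(win), "promoter")
    return pd.Series(labels, index=ocrs.ids, name="context")


def jaccard_bp(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> float:
    """Base-pair Jaccard index: bp(A intersect B) / bp(A union B); 0 when the
    union is empty."""
    a, b = list(a), list(b)
    inter = intersection_bp(a, b)
    union = total_bp(a) + total_bp(b) - inter
    return inter / union if union > 0 else 0.0


def regulatory_domains(
    annotation: GeneAnnotation,
    basal_upstream: int = 5000,
    basal_downstream: int = 1000,
    extension: int = 1_000_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """GREAT-style basal-plus-extension regulatory domains.

    The basal domain spans ``basal_upstream`` bp upstream and
    ``basal_downstream`` bp downstream of the canonical (first) TSS by
    strand; it is then extended in both directions up to ``extension`` bp
    but never into a neighboring gene's basal domain.
    """
    first_tss = annotation.tss.sort_values(["gene_id", "pos"]).groupby("gene_id").first()
    rows = []
    for gid, row in first_tss.iterrows():
        strand = annotation.genes.set_index("gene_id").loc[gid, "strand"]
        pos, chrom = int(row["pos"]), row["chrom"]
        if strand == "-":
            b_start, b_end = pos - basal_downstream, pos + basal_upstream
        else:
            b_start, b_end = pos - basal_upstream, pos + basal_downstream
        rows.append((gid, chrom, max(0, b_start), b_end, pos))
    rows.sort(key=lambda r: (r[1], r[4]))
    domains = []
    for i, (gid, chrom, b_start, b_end, pos) in enumerate(rows):
        lo = b_start - (extension - (pos - b_start))
        hi = b_end + (extension - (b_end - pos))
        lo = max(0, min(b_start, max(lo, pos - extension)))
        hi = max(b_end, min(hi, pos + extension))
        if i > 0 and rows[i - 1][1] == chrom:
            lo = max(lo, min(rows[i - 1][3], b_start))
        if i + 1 < len(rows) and rows[i + 1][1] == chrom:
            hi = min(hi, max(rows[i + 1][2], b_end))
        if chrom_sizes and chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[chrom])
        domains.append(
            RegulatoryDomain(
                gid,
                GenomicInterval(chrom, lo, hi),
                GenomicInterval(chrom, b_start, b_end),
            )
        )
    return domains


def great_enrichment(
    ocrs: OCRSet,
    domains: Sequence[RegulatoryDomain],
    gene_set: set[str],
) -> tuple[float, float]:
    """Binomial OCR-density enrichment of a gene set's regulatory domains.

    With n = OCRs overlapping the union of all domains, k = OCRs overlapping
    the union of the gene set's domains, and pi = bp coverage fraction of
    the set's union within the all-domain union: fold = (k/n) / pi and
    p = P(X >= k) for X ~ Binomial(n, pi).
    """
    if not gene_set:
        raise InputError("gene set is empty")
    known = {d.gene_id for d in domains}
    unknown = gene_set - known
    if unknown:
        raise InputError(f"gene set references unknown genes: {sorted(unknown)[:5]}")
    all_ivs = [d.interval for d in domains]
    set_ivs = [d.interval for d in domains if d.gene_id in gene_set]
    all_union = merge_intervals(all_ivs)
    set_union = merge_intervals(set_ivs)
    bp_all = total_bp(all_union)
    if bp_all == 0:
        raise InputError("regulatory domains cover zero base pairs")
    # restrict the set's coverage to within the all-domain union
    pi = intersection_bp(set_union, all_union) / bp_all

    def hits(union):
        return sum(
            1 for iv in ocrs
            if any(iv.chrom == u.chrom and iv.start < u.end and u.start < iv.end for u in union)
        )

    n = hits(all_union)
    k = hits(set_union)
    if n == 0:
        return 0.0, 1.0
    fold = (k / n) / pi if pi > 0 else np.inf
    p = float(stats.binom.sf(k - 1, n, pi)) if pi > 0 else (1.0 if k == 0 else 0.0)
    return float(fold), min(p, 1.0)


def tss_direct_map(
    cell_means_logcpm: pd.DataFrame,
    ocrs: OCRSet,
    annotation: GeneAnnotation,
    specificity_sets: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-gene cell-type read fractions from TSS-overlapping OCRs.

    ``cell_means_logcpm`` is the residualized log2-CPM averaged per cell
    type (OCR id x cell type); it is back-transformed to the linear scale
    (2**x) before summing per gene over all OCRs overlapping any of the
    gene's TSSs, then row-normalized to fractions. Genes with no
    TSS-overlapping OCR are absent. A gene is called specific to a cell
    type iff at least one of its TSS-overlapping OCRs is in that cell's
    specificity set.
    """
    linear = 2.0 ** cell_means_logcpm
    id_to_row = {oid: i for i, oid in enumerate(ocrs.ids)}
    gene_ocrs: dict[str, set[str]] = {}
    for _, row in annotation.tss.iterrows():
        pos = int(row["pos"])
        probe = GenomicInterval(row["chrom"], pos, pos + 1)
        for i in ocrs.overlapping_indices(probe):
            gene_ocrs.setdefault(row["gene_id"], set()).add(ocrs.ids[i])
    rows, index = [], []
    specific: dict[str, list[str]] = {
        cell: [] for cell in (specificity_sets or {})
    }
    for gid in sorted(gene_ocrs):
        oids = sorted(gene_ocrs[gid])
        sums = linear.loc[oids].sum(axis=0)
        total = sums.sum()
        if total <= 0:
            continue
        rows.append(sums / total)
        index.append(gid)
        if specificity_sets:
            for cell, table in specificity_sets.items():
                if any(o in table.index for o in oids):
                    specific[cell].append(gid)
    fractions = pd.DataFrame(rows, index=index)
    return fractions, specific


def _pad_and_merge(ocrs: Iterable[GenomicInterval], padding: int) -> list[GenomicInterval]:
    padded = [
        GenomicInterval(iv.chrom, max(0, iv.start - padding), iv.end + padding)
        for iv in ocrs
    ]
    return merge_intervals(padded)


def _in_intervals(positions: pd.DataFrame, merged: list[GenomicInterval]) -> np.ndarray:
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        s, e = by_chrom.setdefault(iv.chrom, ([], []))
        s.append(iv.start)
        e.append(iv.end)
    by_chrom = {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in by_chrom.items()}
    out = np.zeros(len(positions), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(positions["chrom"], positions["pos"])):
        if chrom not in by_chrom:
            continue
        s, e = by_chrom[chrom]
        j = np.searchsorted(s, pos, side="right") - 1
        out[i] = j >= 0 and pos < e[j]
    return out


def eqtl_enrichment(
    ocrs: OCRSet,
    variants: pd.DataFrame,
    padding: int = 0,
    n_perm: int = 0,
    seed: int | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> dict:
    """Enrichment of credible-set variants inside (padded) OCRs.

    ``variants`` needs columns chrom, pos, credible (0/1). Builds the 2x2
    table (in padded OCR) x (credible), reports the odds ratio and two-
    sided Fisher exact p; with ``n_perm`` > 0 also an empirical p from a
    null that repositions each OCR uniformly at random on its own
    chromosome, preserving length:
    p_emp = (1 + #{permutations with OR >= observed}) / (1 + n_perm).
    Degenerate tables get a Haldane 0.5 correction for the OR and are
    flagged.
    """
    cred = variants["credible"].astype(bool).to_numpy()
    if not cred.any() or cred.all():
        raise InputError("need both credible and non-credible variants")

    def table_for(merged):
        inside = _in_intervals(variants, merged)
        a = int(np.sum(inside & cred))
        b = int(np.sum(inside & ~cred))
        c = int(np.sum(~inside & cred))
        d = int(np.sum(~inside & ~cred))
        return a, b, c, d

    def odds(a, b, c, d):
        if min(a, b, c, d) == 0:
            return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)), True
        return a * d / (b * c), False

    merged_obs = _pad_and_merge(list(ocrs), padding)
    a, b, c, d = table_for(merged_obs)
    or_obs, corrected = odds(a, b, c, d)
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    result = {
        "odds_ratio": float(or_obs),
        "fisher_p": float(fisher_p),
        "table": (a, b, c, d),
        "haldane_corrected": corrected,
        "empirical_p": None,
    }
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        sizes = dict(chrom_sizes) if chrom_sizes else {}
        for iv in ocrs:
            sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end)
        for chrom, pos in zip(variants["chrom"], variants["pos"]):
            sizes[chrom] = max(sizes.get(chrom, 0), int(pos) + 1)
        hits = 0
        for _ in range(n_perm):
            moved = []
            for iv in ocrs:
                L = len(iv)
                hi = max(1, sizes[iv.chrom] - L)
                s = int(rng.integers(0, hi))
                moved.append(GenomicInterval(iv.chrom, s, s + L))
            or_p, _ = odds(*table_for(_pad_and_merge(moved, padding)))
            if or_p >= or_obs:
                hits += 1
        result["empirical_p"] = (1 + hits) / (1 + n_perm)
    return result
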