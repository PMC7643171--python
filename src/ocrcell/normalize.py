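"""Low-accessibility filtering and promoter-anchored TMM normalization.

Standard TMM computes per-sample scaling factors from trimmed, precision-
weighted log-ratios against a reference sample. Here the factors are
computed only from OCRs that directly overlap an autosomal protein-coding
TSS ("promoter OCRs"): chromatin composition (promoter vs non-promoter
fraction) differs between cell types, and anchoring the factor on promoter
OCRs keeps housekeeping promoters balanced across cell types. To avoid an
arbitrary reference choice, the factor for each sample is the arithmetic
mean of its TMM factor against every other sample as reference, then the
factor vector is rescaled to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError, NormalizationError, PipelineError

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "filter_low",
    "tmm_factor_pair",
    "promoter_tmm",
    "log_cpm",
]


@dataclass
class CountMatrix:
    """OCR x sample matrix of nonnegative integer fragment counts."""

    values: np.ndarray
    ocr_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.ocr_ids), len(self.sample_ids)):
            raise InputError(
                f"count matrix shape {self.values.shape} inconsistent with "
                f"{len(self.ocr_ids)} OCRs x {len(self.sample_ids)} samples"
            )
        if (self.values < 0).any():
            raise InputError("count matrix contains negative entries")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ocr_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.values, list(df.index), list(df.columns))

    def subset_ocrs(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.values[idx], [self.ocr_ids[i] for i in idx], list(self.sample_ids)
        )


@dataclass
class NormalizedMatrix:
    """log2-CPM matrix with the TMM factors and effective library sizes."""

    logcpm: np.ndarray
    ocr_ids: list[str]
    sample_ids: list[str]
    norm_factors: np.ndarray
    effective_lib_sizes: np.ndarray
    prior_count: float = 0.5

    def __post_init__(self):
        gm = np.exp(np.mean(np.log(self.norm_factors)))
        if abs(gm - 1.0) > 1e-6:
            raise InputError(
                f"norm factors must have geometric mean 1 (got {gm:.8f})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.logcpm, index=self.ocr_ids, columns=self.sample_ids)


def filter_low(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    sample_fraction: float = 0.1,
) -> np.ndarray:
    """Indices of OCRs with CPM >= threshold in >= ceil(fraction * n) samples.

    The boundary is inclusive on both the CPM value and the sample count
    ("at least 1 count per million reads in at least 10% of the samples").
    """
    lib = counts.library_sizes
    if (lib <= 0).any():
        raise InputError("every sample must have a positive library size")
    cpm = counts.values / lib * 1e6
    n_required = int(np.ceil(sample_fraction * len(counts.sample_ids)))
    kept = np.flatnonzero((cpm >= cpm_threshold).sum(axis=1) >= n_required)
    if kept.size == 0:
        raise PipelineError("low-accessibility filter removed every OCR")
    return kept


def tmm_factor_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> float:
    """TMM scaling factor of one sample against a reference sample.

    M-values (log2 relative-abundance ratios) are doubly trimmed — the most
    extreme ``logratio_trim`` fraction by M and ``abs_trim`` fraction by
    absolute abundance A are dropped on each side — and the remaining M are
    averaged with inverse delta-method variance weights. Returns a linear
    scale factor (2**weighted-mean-M).
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    keep = (obs > 0) & (ref > 0) & (obs < lib_obs) & (ref < lib_ref)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        raise NormalizationError("no features usable for the TMM pair")
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M for binomial counts
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    from scipy.stats import rankdata

    rm, ra = rankdata(m), rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if abs(f) < 1e-6:
        f = 0.0
    return float(2.0 ** f)


def promoter_tmm(
    counts: CountMatrix,
    promoter_mask: np.ndarray,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
    return_per_reference: bool = False,
):
    """Reference-averaged TMM factors computed on promoter OCRs only.

    ``promoter_mask`` flags OCRs overlapping an autosomal protein-coding
    TSS; only these rows enter the M/A trimming. Library sizes remain the
    full column sums. For each sample the factor is the arithmetic mean of
    its pairwise TMM factor over every choice of reference sample (the
    self-reference contributes exactly 1); factors are then rescaled so
    their geometric mean is 1. Averaging over all references removes the
    arbitrariness of a single reference choice and makes the promoter-
    anchored effective library size exactly invariant to non-promoter
    content when promoter composition is shared.

    With ``return_per_reference`` also returns the samples x references
    factor matrix (diagonal 1), from which the reference-choice standard
    deviation can be read.
    """
    promoter_mask = np.asarray(promoter_mask, dtype=bool)
    if promoter_mask.shape[0] != len(counts.ocr_ids):
        raise InputError("promoter mask length must match the number of OCRs")
    sub = counts.values[promoter_mask]
    if sub.shape[0] < 2:
        raise NormalizationError("need >=2 promoter OCRs for TMM")
    lib = counts.library_sizes.astype(float)
    n = len(counts.sample_ids)
    for j in range(n):
        if sub[:, j].sum() == 0:
            raise NormalizationError(
                f"sample {counts.sample_ids[j]} has all-zero promoter counts"
            )
    per_ref = np.ones((n, n))
    for j in range(n):
        for r in range(n):
            if r == j:
                continue
            per_ref[j, r] = tmm_factor_pair(
                sub[:, j], sub[:, r], lib[j], lib[r], logratio_trim, abs_trim
            )
    factors = np.mean(per_ref, axis=1)
    factors = factors / np.exp(np.mean(np.log(factors)))
    if return_per_reference:
        return factors, per_ref
    return factors


def log_cpm(
    counts: CountMatrix,
    norm_factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    logcpm[i, s] = log2((y + prior) / (lib_s * f_s + 2 * prior) * 1e6).
    """
    if norm_factors is None:
        norm_factors = np.ones(len(counts.sample_ids))
    norm_factors = np.asarray(norm_factors, dtype=float)
    if (norm_factors <= 0).any():
        raise NormalizationError("normalization factors must be positive")
    eff = counts.library_sizes * norm_factors
    if (eff <= 0).any():
        raise NormalizationError("effective library sizes must be positive")
    logcpm = np.log2(
        (counts.values + prior_count) / (eff + 2.0 * prior_count) * 1e6
    )
    return NormalizedMatrix(
        logcpm=logcpm,
        ocr_ids=list(counts.ocr_ids),
        sample_ids=list(counts.sample_ids),
        norm_factors=norm_factors / np.exp(np.mean(np.log(norm_factors))),
        effective_lib_sizes=eff,
        prior_count=prior_count,
    )
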