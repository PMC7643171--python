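"""Covariate preparation, screening and selection for the accessibility model.

The accessibility model is, per OCR,

    accessibility ~ cell_type:brain_region + sex + FRiP

i.e. a one-hot cell-by-region group factor (12 levels, no intercept), a sex
indicator and a numeric FRiP term — 14 degrees of freedom in the study
design. Additional covariates are screened by correlation with high-variance
principal components (computed within cell type) and admitted by a net-BIC
criterion: a covariate enters only if the number of OCRs whose BIC improves
by >=2 exceeds the number whose BIC worsens by >=2 by at least 5% of OCRs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError

__all__ = [
    "ModelSpec",
    "build_design",
    "center_metrics",
    "pca_screen",
    "bic_forward_select",
    "variance_fractions",
]

CELL_TYPES = ("GLU", "GABA", "OLIG", "MGAS")
REGIONS = ("ACC", "DLPFC", "PVC")


@dataclass
class ModelSpec:
    """Design specification: group factor + extra factors + numeric terms.

    ``df_total`` counts all estimated mean parameters: one per group level
    (cell-means coding, no intercept), (levels - 1) per extra factor, and
    one per numeric covariate.
    """

    group_levels: tuple[str, ...]
    extra_factors: dict[str, tuple[str, ...]] = field(default_factory=dict)
    numeric_covariates: tuple[str, ...] = ()

    @property
    def df_total(self) -> int:
        return (
            len(self.group_levels)
            + sum(len(lv) - 1 for lv in self.extra_factors.values())
            + len(self.numeric_covariates)
        )

    @classmethod
    def study_default(cls) -> "ModelSpec":
        """The final cohort model: 12 cell-by-region groups + sex + FRiP."""
        groups = tuple(f"{c}_{r}" for c in CELL_TYPES for r in REGIONS)
        return cls(
            group_levels=groups,
            extra_factors={"sex": ("M", "F")},
            numeric_covariates=("frip",),
        )


def build_design(
    metadata: pd.DataFrame, spec: ModelSpec, group_col: str = "group"
) -> tuple[np.ndarray, list[str]]:
    """Design matrix under cell-means coding of the group factor.

    ``metadata[group_col]`` holds the cell-by-region group label; extra
    factors are dummy-coded against their first level; numeric covariates
    are taken as-is.
    """
    n = len(metadata)
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups = metadata[group_col].astype(str).values
    unknown = set(groups) - set(spec.group_levels)
    if unknown:
        raise InputError(f"unknown group levels: {sorted(unknown)}")
    for lvl in spec.group_levels:
        cols.append((groups == lvl).astype(float))
        names.append(f"group[{lvl}]")
    for fac, levels in spec.extra_factors.items():
        vals = metadata[fac].astype(str).values
        for lvl in levels[1:]:
            cols.append((vals == lvl).astype(float))
            names.append(f"{fac}[{lvl}]")
    for cov in spec.numeric_covariates:
        cols.append(metadata[cov].astype(float).values)
        names.append(cov)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names


def center_metrics(
    metadata: pd.DataFrame,
    metric_names: list[str],
    group_by: str = "cell_type",
    mode: str = "ratio",
) -> pd.DataFrame:
    """Normalize QC metrics to the per-cell-type median.

    Ratio mode divides by the group median (requires strictly positive
    values); offset mode subtracts it.
    """
    out = metadata.copy()
    for name in metric_names:
        vals = out[name].astype(float)
        if mode == "ratio":
            if (vals <= 0).any():
                raise InputError(
                    f"metric {name} has nonpositive values; use mode='offset'"
                )
            out[name] = vals / vals.groupby(out[group_by]).transform("median")
        elif mode == "offset":
            out[name] = vals - vals.groupby(out[group_by]).transform("median")
        else:
            raise InputError(f"unknown centering mode {mode!r}")
    return out


def pca_screen(
    logcpm: np.ndarray,
    metadata: pd.DataFrame,
    candidates: pd.DataFrame,
    cell_col: str = "cell_type",
    var_threshold: float = 0.01,
    fdr: float = 0.2,
) -> tuple[list[str], pd.DataFrame]:
    """Screen candidate covariates by correlation with high-variance PCs.

    PCA is run separately within each cell type (otherwise the leading
    components simply encode cell identity). Components explaining more
    than ``var_threshold`` of the variance are kept; every candidate is
    Pearson-correlated with every kept PC; Benjamini-Hochberg adjustment is
    applied across all (candidate, PC, cell type) tests; a candidate passes
    if any adjusted p <= ``fdr``.

    Returns the selected candidate names and the full test table.
    """
    rows = []
    for cell, sub in metadata.groupby(cell_col, sort=True):
        idx = sub.index.to_numpy()
        pos = [metadata.index.get_loc(i) for i in idx]
        if len(pos) < 3:
            warnings.warn(
                f"cell type {cell}: fewer than 3 samples, PCA screen skipped"
            )
            continue
        mat = logcpm[:, pos].T  # samples x OCRs
        mat = mat - mat.mean(axis=0)
        u, s, _ = np.linalg.svd(mat, full_matrices=False)
        evr = s**2 / np.sum(s**2)
        keep = np.flatnonzero(evr > var_threshold)
        scores = u[:, keep] * s[keep]
        for k_i, k in enumerate(keep):
            for cand in candidates.columns:
                x = candidates.loc[idx, cand].astype(float).to_numpy()
                if np.std(x) == 0 or np.std(scores[:, k_i]) == 0:
                    continue
                r, p = stats.pearsonr(x, scores[:, k_i])
                rows.append(
                    {"cell_type": cell, "pc": int(k) + 1, "evr": float(evr[k]),
                     "candidate": cand, "r": r, "p": p}
                )
    table = pd.DataFrame(rows)
    if table.empty:
        return [], table
    table["p_adj"] = multipletests(table["p"].values, method="fdr_bh")[1]
    selected = sorted(table.loc[table["p_adj"] <= fdr, "candidate"].unique())
    return selected, table


def _batched_rss(X: np.ndarray, Y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Residual sum of squares of per-row OLS/WLS fits of Y (G x n) on X (n x k)."""
    if w is not None:
        sw = np.sqrt(np.asarray(w, dtype=float))
        X = X * sw[:, None]
        Y = Y * sw[None, :]
    beta, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return np.sum(resid**2, axis=0)


def _gaussian_bic(rss: np.ndarray, n: int, k: int) -> np.ndarray:
    """BIC from the Gaussian log-likelihood; k coefficients + 1 variance."""
    rss = np.maximum(rss, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return -2.0 * ll + (k + 1) * np.log(n)


def _candidate_columns(values) -> np.ndarray:
    """Numeric candidates become one column; categoricals dummy-code."""
    s = pd.Series(values)
    if s.dtype.kind in "biufc":
        return s.astype(float).to_numpy()[:, None]
    levels = sorted(s.astype(str).unique())
    return np.column_stack([(s.astype(str) == lv).astype(float) for lv in levels[1:]])


def bic_forward_select(
    logcpm: np.ndarray,
    base_design: np.ndarray,
    candidates: pd.DataFrame,
    sample_weights: np.ndarray | None = None,
    net_threshold: float = 0.05,
    bic_delta: float = 2.0,
    test_squares: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy net-BIC forward selection of covariates.

    For each candidate, per-OCR linear models are fitted with and without
    it; ``improved`` counts OCRs whose BIC drops by >= ``bic_delta`` (the
    lower bound of positive evidence), ``worse`` counts OCRs whose BIC
    rises by >= ``bic_delta``; the candidate with the largest net share
    (improved - worse) / #OCRs is added if the share is >= ``net_threshold``,
    and the remaining candidates are re-tested against the grown model.
    After numeric candidates are exhausted, squared versions of the selected
    numeric covariates are tested the same way. Ties in net share break
    lexicographically on the candidate name.

    Returns the ordered selected names and a per-round report table.
    """
    G, n = logcpm.shape
    if n <= base_design.shape[1]:
        raise InputError("base model is not estimable: n_samples <= df")
    X = base_design.copy()
    remaining = list(candidates.columns)
    selected: list[str] = []
    report_rows = []
    round_no = 0

    def run_rounds(pool: dict[str, np.ndarray]):
        nonlocal X, round_no
        pool = dict(pool)
        while pool:
            round_no += 1
            rss_base = _batched_rss(X, logcpm, sample_weights)
            bic_base = _gaussian_bic(rss_base, n, X.shape[1])
            shares = {}
            for name, cols in pool.items():
                Xc = np.column_stack([X, cols])
                if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
                    warnings.warn(f"candidate {name} makes the design singular; skipped")
                    continue
                bic_c = _gaussian_bic(
                    _batched_rss(Xc, logcpm, sample_weights), n, Xc.shape[1]
                )
                delta = bic_c - bic_base
                improved = int(np.sum(delta <= -bic_delta))
                worse = int(np.sum(delta >= bic_delta))
                share = (improved - worse) / G
                shares[name] = share
                report_rows.append(
                    {"round": round_no, "candidate": name, "improved": improved,
                     "worse": worse, "net_share": share}
                )
            qualifying = {k: v for k, v in shares.items() if v >= net_threshold}
            if not qualifying:
                break
            best = min(qualifying, key=lambda k: (-qualifying[k], k))
            selected.append(best)
            X = np.column_stack([X, pool.pop(best)])

    run_rounds({name: _candidate_columns(candidates[name]) for name in remaining})

    if test_squares:
        sq_pool = {}
        for name in selected:
            s = pd.Series(candidates[name]) if name in candidates else None
            if s is not None and s.dtype.kind in "biufc":
                sq_pool[f"{name}^2"] = (s.astype(float) ** 2).to_numpy()[:, None]
        if sq_pool:
            run_rounds(sq_pool)

    return selected, pd.DataFrame(report_rows)


def variance_fractions(
    logcpm: np.ndarray,
    covariates: pd.DataFrame,
    order: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-OCR decomposition of variance into covariate terms + residual.

    Sequential (type-I) ANOVA in the given term order: each term's sum of
    squares is the drop in residual SS when it is added to the model built
    from the preceding terms (intercept first). Fractions are SS over the
    centered total SS, so fractions + residual sum to 1 exactly for every
    OCR; on balanced designs this coincides with the type-II decomposition.
    Categorical columns are dummy-coded, numeric columns enter as-is.

    Returns (per-OCR fraction table, median fraction per term).
    """
    terms = order if order is not None else list(covariates.columns)
    n = len(covariates)
    G = logcpm.shape[0]
    X = np.ones((n, 1))
    # collinearity check on the full design
    blocks = {t: _candidate_columns(covariates[t]) for t in terms}
    full = np.column_stack([X] + [blocks[t] for t in terms])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        for i, a in enumerate(terms):
            for b in terms[i + 1:]:
                pair = np.column_stack([X, blocks[a], blocks[b]])
                if np.linalg.matrix_rank(pair) < pair.shape[1]:
                    raise InputError(f"collinear covariates: {a} and {b}")
        raise InputError("design matrix is rank deficient")
    y_centered = logcpm - logcpm.mean(axis=1, keepdims=True)
    tss = np.sum(y_centered**2, axis=1)
    tss = np.where(tss == 0, 1.0, tss)
    rss_prev = _batched_rss(X, logcpm)
    fracs = {}
    for t in terms:
        X = np.column_stack([X, blocks[t]])
        rss = _batched_rss(X, logcpm)
        fracs[t] = np.clip((rss_prev - rss) / tss, 0.0, 1.0)
        rss_prev = rss
    residual = rss_prev / tss
    table = pd.DataFrame(fracs)
    table["residual"] = residual
    # renormalize away accumulated rounding so rows sum to 1 exactly
    table = table.div(table.sum(axis=1), axis=0)
    medians = table.median(axis=0)
    return table, medians
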