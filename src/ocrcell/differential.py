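"""Precision-weighted differential accessibility and specificity set algebra.

log2-CPM values are modeled per OCR by weighted least squares. Observation
weights follow the voom recipe: a mean-variance trend (sqrt residual sd vs
average log-count) is smoothed with lowess and each observation's weight is
the predicted sqrt-sd at its fitted log-count, raised to the power -4.
Sample weights come from one round of per-sample residual-variance
estimation, normalized to geometric mean 1; the combined weight is their
product. Contrast tests use empirical-Bayes variance moderation: per-OCR
residual variances are shrunk toward a common prior fitted by the method of
moments on log variances (scaled inverse-chi-square prior), giving moderated
t statistics with augmented degrees of freedom.

Cell specificity is set algebra over the six pairwise cell contrasts: an OCR
is specific to cell X iff it is significantly more accessible in X than in
each of the other three cell types (FDR 5% within contrast), with the
reported statistics taken from the least significant of the comparisons.
The neuronal / non-neuronal sets are unions of two-way intersections, e.g.
Neuron = (GLU>OLIG and GLU>MGAS) or (GABA>OLIG and GABA>MGAS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .normalize import CountMatrix, NormalizedMatrix, log_cpm

__all__ = [
    "PrecisionWeights",
    "DifferentialResult",
    "SpecificitySets",
    "voom_weights",
    "fit_contrasts",
    "build_cell_pair_contrasts",
    "build_region_contrasts",
    "pair_result",
    "cell_specific_sets",
    "group_specific_sets",
    "region_specific_sets",
    "residualize",
]

NEURONAL = ("GLU", "GABA")
NON_NEURONAL = ("OLIG", "MGAS")


@dataclass
class PrecisionWeights:
    """Observation-level x sample-level precision weights."""

    observation_weights: np.ndarray  # OCR x sample, includes sample weights
    sample_weights: np.ndarray
    trend: tuple[np.ndarray, np.ndarray]  # (mean log-count grid, sqrt-sd fit)

    def __post_init__(self):
        if not np.all(np.isfinite(self.observation_weights)) or np.any(
            self.observation_weights <= 0
        ):
            raise InputError("observation weights must be finite and positive")


@dataclass
class DifferentialResult:
    """Per-OCR effect sizes and moderated tests for one contrast."""

    table: pd.DataFrame  # index = ocr_id; columns log2fc, t, p, fdr
    contrast_id: str

    def __post_init__(self):
        # BH-adjusted values must be monotone nondecreasing in p
        t = self.table.sort_values("p")
        if not np.all(np.diff(t["fdr"].values) >= -1e-12):
            raise InputError("FDR values are not monotone in p")


@dataclass
class SpecificitySets:
    """Cell-, group- and region-specific OCR sets with reported statistics."""

    cell_sets: dict[str, pd.DataFrame] = field(default_factory=dict)
    group_sets: dict[str, pd.DataFrame] = field(default_factory=dict)
    region_sets: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)


def voom_weights(
    counts: CountMatrix,
    norm_factors: np.ndarray,
    design: np.ndarray,
    span: float = 0.5,
    prior_count: float = 0.5,
) -> tuple[PrecisionWeights, NormalizedMatrix]:
    """Estimate precision weights from the mean-variance trend of log-CPM."""
    norm = log_cpm(counts, norm_factors, prior_count=prior_count)
    Y = norm.logcpm
    G, n = Y.shape
    k = np.linalg.matrix_rank(design)
    if design.shape[1] != k:
        raise InputError("design matrix is not full rank")
    df_resid = n - k
    if df_resid < 2:
        raise InputError("need at least 2 residual degrees of freedom")
    lib = norm.effective_lib_sizes
    beta, _, _, _ = np.linalg.lstsq(design, Y.T, rcond=None)
    fitted = (design @ beta).T
    resid = Y - fitted
    sigma = np.sqrt(np.sum(resid**2, axis=1) / df_resid)
    # mean-variance trend: sqrt residual sd vs average log2 count
    sx = Y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    ok = np.isfinite(sx) & np.isfinite(sy) & (sigma > 0)
    smoothed = sm_lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    gx, gy = smoothed[:, 0], np.maximum(smoothed[:, 1], 1e-6)
    # predicted sqrt-sd at each observation's fitted log-count
    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, gx, gy)
    w_obs = pred**-4.0
    # one round of sample-level heteroskedasticity estimation
    z = resid * np.sqrt(w_obs)
    var_s = np.mean(z**2, axis=0)
    var_s = var_s / np.exp(np.mean(np.log(var_s)))
    sw = 1.0 / var_s
    sw = sw / np.exp(np.mean(np.log(sw)))
    combined = w_obs * sw[None, :]
    return (
        PrecisionWeights(observation_weights=combined, sample_weights=sw, trend=(gx, gy)),
        norm,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to sample variances.

    Returns (prior df d0, prior variance s0^2) of the scaled
    inverse-chi-square prior on the true variances.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = np.exp(emean)
    return float(d0), float(s0)


def fit_contrasts(
    logcpm: np.ndarray,
    weights: np.ndarray | None,
    design: np.ndarray,
    contrasts: dict[str, np.ndarray],
    ocr_ids: list[str] | None = None,
    moderate: bool = True,
) -> dict[str, DifferentialResult]:
    """Weighted least squares per OCR with moderated contrast tests.

    ``contrasts`` maps a contrast id to a coefficient vector c; the reported
    effect is c'beta (log2 fold change under log2-CPM), tested against zero
    with an empirical-Bayes moderated t. FDR is Benjamini-Hochberg within
    each contrast. Set ``moderate=False`` for plain WLS t-tests.
    """
    Y = np.asarray(logcpm, dtype=float)
    G, n = Y.shape
    k = design.shape[1]
    if np.linalg.matrix_rank(design) < k:
        raise InputError("design matrix is not full rank")
    df_resid = n - k
    if df_resid < 1:
        raise InputError("no residual degrees of freedom")
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        if c.shape != (k,):
            raise InputError(f"contrast {name}: length {c.size} != {k} coefficients")
        if np.all(c == 0):
            raise InputError(f"contrast {name} is identically zero")
    W = np.ones_like(Y) if weights is None else np.asarray(weights, dtype=float)
    # batched weighted normal equations
    XtWX = np.einsum("gn,nj,nk->gjk", W, design, design)
    XtWy = np.einsum("gn,nj,gn->gj", W, design, Y)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]  # G x k
    fitted = beta @ design.T
    rss = np.sum(W * (Y - fitted) ** 2, axis=1)
    s2 = rss / df_resid
    XtWX_inv = np.linalg.inv(XtWX)
    if moderate:
        d0, s0 = fit_f_dist(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full(G, s0)
            df_total = 1e6
        else:
            s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
            df_total = min(df_resid + d0, 1e6)
    else:
        s2_post = s2
        df_total = df_resid
    ids = ocr_ids if ocr_ids is not None else [f"OCR_{i}" for i in range(G)]
    out = {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        est = beta @ c
        vu = np.einsum("j,gjk,k->g", c, XtWX_inv, c)
        se = np.sqrt(vu * s2_post)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        out[name] = DifferentialResult(
            pd.DataFrame({"log2fc": est, "t": t, "p": p, "fdr": fdr}, index=ids),
            contrast_id=name,
        )
    return out


def build_cell_pair_contrasts(
    coef_names: list[str],
    cell_types: tuple[str, ...] = ("GLU", "GABA", "OLIG", "MGAS"),
    regions: tuple[str, ...] = ("ACC", "DLPFC", "PVC"),
) -> dict[tuple[str, str], np.ndarray]:
    """Region-summed pairwise cell contrasts.

    For the ordered pair (A, B) the contrast is the average over regions of
    group[A_r] - group[B_r], so a positive effect means "more accessible in
    A than B" with the same within-region pairing the study uses.
    """
    k = len(coef_names)
    out = {}
    for i, a in enumerate(cell_types):
        for b in cell_types[i + 1:]:
            c = np.zeros(k)
            for r in regions:
                c[coef_names.index(f"group[{a}_{r}]")] += 1.0 / len(regions)
                c[coef_names.index(f"group[{b}_{r}]")] -= 1.0 / len(regions)
            out[(a, b)] = c
    return out


def build_region_contrasts(
    coef_names: list[str],
    cell_type: str,
    regions: tuple[str, ...] = ("ACC", "DLPFC", "PVC"),
) -> dict[str, np.ndarray]:
    """Within a cell type: each region vs the mean of the other regions."""
    if len(regions) < 2:
        raise InputError("need at least 2 regions for a regional contrast")
    k = len(coef_names)
    out = {}
    for r in regions:
        c = np.zeros(k)
        c[coef_names.index(f"group[{cell_type}_{r}]")] = 1.0
        others = [x for x in regions if x != r]
        for o in others:
            c[coef_names.index(f"group[{cell_type}_{o}]")] = -1.0 / len(others)
        out[r] = c
    return out


def pair_result(
    results: dict[tuple[str, str], DifferentialResult], a: str, b: str
) -> pd.DataFrame:
    """Contrast table oriented so positive log2fc means 'more accessible in a'."""
    if (a, b) in results:
        return results[(a, b)].table
    if (b, a) in results:
        t = results[(b, a)].table.copy()
        t["log2fc"] = -t["log2fc"]
        t["t"] = -t["t"]
        return t
    raise InputError(f"missing pairwise contrast for ({a}, {b})")


def _least_significant(tables: list[pd.DataFrame], mask: np.ndarray) -> pd.DataFrame:
    """Row-wise statistics of the least significant (max p) comparison.

    Ties on p break toward the smallest absolute log2 fold change.
    """
    p = np.stack([t["p"].values for t in tables], axis=1)
    fc = np.stack([t["log2fc"].values for t in tables], axis=1)
    pick = np.empty(p.shape[0], dtype=int)
    for i in range(p.shape[0]):
        cand = np.flatnonzero(p[i] == p[i].max())
        pick[i] = cand[np.argmin(np.abs(fc[i, cand]))]
    rows = {}
    for col in ("log2fc", "t", "p", "fdr"):
        vals = np.stack([t[col].values for t in tables], axis=1)
        rows[col] = vals[np.arange(len(pick)), pick]
    out = pd.DataFrame(rows, index=tables[0].index)
    return out.loc[mask]


def cell_specific_sets(
    results: dict[tuple[str, str], DifferentialResult],
    fdr: float = 0.05,
    cell_types: tuple[str, ...] = ("GLU", "GABA", "OLIG", "MGAS"),
) -> dict[str, pd.DataFrame]:
    """OCRs significantly more accessible in one cell than in each other cell.

    Membership requires FDR < ``fdr`` and a positive fold change against
    every other cell type; the four sets are pairwise disjoint by
    construction. Reported statistics come from the least significant of the
    three comparisons.
    """
    out = {}
    for x in cell_types:
        tables = [pair_result(results, x, y) for y in cell_types if y != x]
        mask = np.ones(len(tables[0]), dtype=bool)
        for t in tables:
            mask &= (t["fdr"].values < fdr) & (t["log2fc"].values > 0)
        out[x] = _least_significant(tables, mask)
    return out


def group_specific_sets(
    results: dict[tuple[str, str], DifferentialResult],
    fdr: float = 0.05,
    neuronal: tuple[str, str] = NEURONAL,
    non_neuronal: tuple[str, str] = NON_NEURONAL,
) -> dict[str, pd.DataFrame]:
    """Neuronal / non-neuronal OCR sets as unions of two-way intersections.

    Neuron = union over neuronal cells N of {OCRs significantly more
    accessible in N than in each non-neuronal cell}; nonNeuron is the
    mirror image. Reported statistics are from the least significant
    comparison of the best satisfied branch.
    """
    def one_side(cells, others):
        branch_masks, branch_tables = [], []
        for x in cells:
            tables = [pair_result(results, x, y) for y in others]
            mask = np.ones(len(tables[0]), dtype=bool)
            for t in tables:
                mask &= (t["fdr"].values < fdr) & (t["log2fc"].values > 0)
            branch_masks.append(mask)
            branch_tables.append(_least_significant(tables, np.ones_like(mask)))
        member = np.zeros_like(branch_masks[0])
        for m in branch_masks:
            member |= m
        # pick, per OCR, the satisfied branch whose worst comparison is best
        p_branch = np.stack(
            [np.where(m, t["p"].values, np.inf) for m, t in zip(branch_masks, branch_tables)],
            axis=1,
        )
        pick = np.argmin(p_branch, axis=1)
        rows = {
            col: np.stack([t[col].values for t in branch_tables], axis=1)[
                np.arange(len(pick)), pick
            ]
            for col in ("log2fc", "t", "p", "fdr")
        }
        return pd.DataFrame(rows, index=branch_tables[0].index).loc[member]

    return {
        "Neuron": one_side(neuronal, non_neuronal),
        "nonNeuron": one_side(non_neuronal, neuronal),
    }


def region_specific_sets(
    results: dict[str, DifferentialResult],
    cell_ocr_mask: np.ndarray,
    fdr: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-region sets of OCRs more accessible in one region within a cell.

    ``results`` holds the region-vs-mean-of-others contrasts for the cell
    type; FDR adjustment is applied only over the OCRs in
    ``cell_ocr_mask`` (consensus OCRs overlapping OCRs called in that cell
    type), and only masked OCRs can be reported.
    """
    if len(results) < 2:
        raise InputError("need contrasts for at least 2 regions")
    cell_ocr_mask = np.asarray(cell_ocr_mask, dtype=bool)
    out = {}
    for region, res in results.items():
        t = res.table
        if cell_ocr_mask.shape[0] != len(t):
            raise InputError("mask length must match the number of OCRs")
        sub = t.loc[cell_ocr_mask, ["log2fc", "t", "p"]].copy()
        sub["fdr"] = multipletests(sub["p"].values, method="fdr_bh")[1]
        out[region] = sub.loc[(sub["fdr"] < fdr) & (sub["log2fc"] > 0)]
    return out


def residualize(
    logcpm: np.ndarray,
    design: np.ndarray,
    coef_names: list[str],
    remove: list[str],
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Subtract the estimated effect of nuisance covariates from log-CPM.

    ``remove`` names covariates (e.g. ["sex", "frip"]); every design column
    named ``cov`` or ``cov[level]`` is matched. The full model is fitted and
    only the matched columns' contribution is subtracted, retaining the cell
    type and brain region structure.
    """
    cols = []
    for label in remove:
        matched = [
            i for i, nm in enumerate(coef_names)
            if nm == label or nm.startswith(f"{label}[")
        ]
        if not matched:
            raise InputError(f"unknown covariate label {label!r}")
        cols.extend(matched)
    Y = np.asarray(logcpm, dtype=float)
    if weights is None:
        beta, _, _, _ = np.linalg.lstsq(design, Y.T, rcond=None)
        beta = beta.T  # G x k
    else:
        W = np.asarray(weights, dtype=float)
        XtWX = np.einsum("gn,nj,nk->gjk", W, design, design)
        XtWy = np.einsum("gn,nj,gn->gj", W, design, Y)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    return Y - beta[:, cols] @ design[:, cols].T
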