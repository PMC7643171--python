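"""Proportion of non-null tests (pi1 = 1 - pi0).

pi1 quantifies how different two sample groups are: from the p-values of a
pairwise differential contrast, pi0 (the fraction of truly null OCRs) is
estimated by the smoother method — the natural estimator
pi0(lambda) = #{p > lambda} / ((1 - lambda) n) is computed over a lambda
grid, a cubic smoother is fitted, and the value at the largest lambda is
taken. The pairwise pi1 matrix over all 12 cell-type-by-region groups (66
unordered comparisons) summarizes group dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .differential import fit_contrasts
from .exceptions import InputError

__all__ = ["Pi1Result", "estimate_pi0", "pairwise_pi1", "aggregate_pi1"]


@dataclass
class Pi1Result:
    pi0: float
    pi1: float
    n_tests: int
    method: str

    def __post_init__(self):
        if not (0.0 <= self.pi0 <= 1.0):
            raise InputError(f"pi0 out of [0,1]: {self.pi0}")
        if abs(self.pi1 - (1.0 - self.pi0)) > 1e-12:
            raise InputError("pi1 must equal 1 - pi0 exactly")


def estimate_pi0(
    pvalues: np.ndarray,
    method: str = "smoother",
    lambdas: np.ndarray | None = None,
    fixed_lambda: float = 0.5,
) -> Pi1Result:
    """Estimate pi0 from a p-value vector.

    ``smoother``: pi0(lambda) over lambda = 0.05, 0.10, ..., 0.95, cubic
    polynomial smooth, evaluated at the largest lambda, clamped to [0, 1].
    ``fixed``: the single-lambda estimator at ``fixed_lambda``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0 or np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    n = p.size
    if n < 100:
        warnings.warn(f"pi0 estimate from only {n} p-values is unstable")
    if method == "smoother":
        if lambdas is None:
            lambdas = np.arange(0.05, 0.951, 0.05)
        pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        # precision weights: var(pi0(lambda)) scales like 1/(1 - lambda)
        coeffs = np.polyfit(lambdas, pi0_lam, deg=3, w=1.0 - lambdas)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    elif method == "fixed":
        pi0 = float(np.mean(p > fixed_lambda) / (1.0 - fixed_lambda))
    else:
        raise InputError(f"unknown pi0 method {method!r}")
    pi0 = min(max(pi0, 0.0), 1.0)
    return Pi1Result(pi0=pi0, pi1=1.0 - pi0, n_tests=n, method=method)


def pairwise_pi1(
    logcpm: np.ndarray,
    weights: np.ndarray | None,
    design: np.ndarray,
    coef_names: list[str],
    group_levels: list[str],
    ocr_ids: list[str] | None = None,
    method: str = "smoother",
) -> pd.DataFrame:
    """Symmetric pi1 matrix over all unordered group pairs.

    Each pair is tested with the contrast group_a - group_b on the full
    fitted model; pi1 is estimated from that contrast's p-values. For 12
    groups this yields 66 comparisons.
    """
    for g in group_levels:
        if f"group[{g}]" not in coef_names:
            raise InputError(f"group {g} absent from the design")
    contrasts = {}
    for a, b in combinations(group_levels, 2):
        c = np.zeros(len(coef_names))
        c[coef_names.index(f"group[{a}]")] = 1.0
        c[coef_names.index(f"group[{b}]")] = -1.0
        contrasts[f"{a}|{b}"] = c
    results = fit_contrasts(logcpm, weights, design, contrasts, ocr_ids=ocr_ids)
    mat = pd.DataFrame(np.nan, index=group_levels, columns=group_levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for key, res in results.items():
            a, b = key.split("|")
            pi1 = estimate_pi0(res.table["p"].values, method=method).pi1
            mat.loc[a, b] = pi1
            mat.loc[b, a] = pi1
    return mat


def aggregate_pi1(
    matrix: pd.DataFrame, groups_a: list[str], groups_b: list[str]
) -> float:
    """Median pi1 over all pairs with one group from each side (e.g. all
    neuronal vs non-neuronal group pairs)."""
    vals = [
        matrix.loc[a, b]
        for a in groups_a
        for b in groups_b
        if a != b and np.isfinite(matrix.loc[a, b])
    ]
    if not vals:
        raise InputError("no pairs to aggregate")
    return float(np.median(vals))
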