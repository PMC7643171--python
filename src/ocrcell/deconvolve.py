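"""Marker-based deconvolution of bulk chromatin data and the case-control
composition workflow.

Marker OCRs are cell-specific OCRs passing stringent thresholds (FDR < 5%
and log2 fold change > 2 against every other cell type). Bulk cell-type
proportions are estimated per sample by a linear mixing model on the
linear-scale CPM of marker OCRs: minimize ||y - R theta|| subject to
theta >= 0 and sum(theta) = 1. The case-control workflow then asks how
much statistical signal (pi1) a diagnosis contrast carries with and without
composition covariates, the latter admitted through the same net-BIC
forward selection used for the cohort model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .covariates import bic_forward_select
from .differential import DifferentialResult, fit_contrasts, pair_result
from .exceptions import InputError
from .normalize import CountMatrix, log_cpm
from .pi1 import estimate_pi0

__all__ = [
    "MarkerPanel",
    "MixingEstimate",
    "select_markers",
    "estimate_proportions",
    "casecontrol_workflow",
]


@dataclass
class MarkerPanel:
    """Disjoint per-cell-type marker OCR lists with selection thresholds."""

    markers: dict[str, list[str]]
    fdr: float = 0.05
    min_log2fc: float = 2.0

    def __post_init__(self):
        seen: set[str] = set()
        for cell, ids in self.markers.items():
            dup = seen & set(ids)
            if dup:
                raise InputError(f"marker sets overlap at {sorted(dup)[:5]}")
            seen |= set(ids)

    @property
    def all_markers(self) -> list[str]:
        return [m for ids in self.markers.values() for m in ids]


@dataclass
class MixingEstimate:
    """Estimated cell-type proportions per bulk sample."""

    proportions: pd.DataFrame  # sample x cell type
    residual_norm: pd.Series

    def __post_init__(self):
        vals = self.proportions.values
        if (vals < -1e-9).any():
            raise InputError("proportions must be nonnegative")
        if np.abs(vals.sum(axis=1) - 1.0).max() > 1e-6:
            raise InputError("proportions must sum to 1 per sample")


def select_markers(
    results: dict[tuple[str, str], DifferentialResult],
    fdr: float = 0.05,
    min_log2fc: float = 2.0,
    cell_types: tuple[str, ...] = ("GLU", "GABA", "OLIG", "MGAS"),
) -> MarkerPanel:
    """Marker OCRs: FDR < ``fdr`` and log2fc > ``min_log2fc`` for one cell
    type against each of the others (pairwise cell contrasts)."""
    markers: dict[str, list[str]] = {}
    for x in cell_types:
        tables = [pair_result(results, x, y) for y in cell_types if y != x]
        mask = np.ones(len(tables[0]), dtype=bool)
        for t in tables:
            mask &= (t["fdr"].values < fdr) & (t["log2fc"].values > min_log2fc)
        ids = list(tables[0].index[mask])
        if not ids:
            raise InputError(
                f"no marker OCRs for {x}; deconvolution is impossible"
            )
        markers[x] = ids
    return MarkerPanel(markers=markers, fdr=fdr, min_log2fc=min_log2fc)


def _simplex_ls(R: np.ndarray, y: np.ndarray) -> np.ndarray:
    """min ||y - R theta|| s.t. theta >= 0, sum(theta) = 1.

    Solved by nonnegative least squares on the system augmented with a
    strongly weighted sum-to-one row, then exact renormalization.
    """
    scale = max(np.abs(y).max(), 1.0)
    kappa = 1e4 * scale
    A = np.vstack([R, kappa * np.ones((1, R.shape[1]))])
    b = np.concatenate([y, [kappa]])
    theta, _ = nnls(A, b)
    s = theta.sum()
    if s <= 0:
        raise InputError("mixing solver returned a zero proportion vector")
    return theta / s


def estimate_proportions(
    bulk: CountMatrix,
    reference: pd.DataFrame,
    panel: MarkerPanel,
) -> MixingEstimate:
    """Linear mixing estimate of cell proportions from marker OCR CPM.

    ``reference`` is the marker-OCR x cell-type matrix of linear-scale mean
    accessibility (CPM) in the sorted reference data; bulk samples are
    converted to CPM on the same marker OCRs and each is projected onto the
    simplex-constrained span of the reference profiles.
    """
    marker_ids = [m for m in panel.all_markers if m in reference.index]
    missing = set(panel.all_markers) - set(reference.index)
    if missing:
        raise InputError(f"reference lacks marker OCRs: {sorted(missing)[:5]}")
    missing_bulk = set(marker_ids) - set(bulk.ocr_ids)
    if missing_bulk:
        raise InputError(f"bulk matrix lacks marker OCRs: {sorted(missing_bulk)[:5]}")
    R = reference.loc[marker_ids].values.astype(float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise InputError("reference profile matrix is rank deficient")
    bulk_df = bulk.to_frame()
    lib = bulk_df.sum(axis=0).values.astype(float)
    cpm = bulk_df.loc[marker_ids].values / lib * 1e6
    thetas, resid = [], []
    for j, sample in enumerate(bulk.sample_ids):
        theta = _simplex_ls(R, cpm[:, j])
        thetas.append(theta)
        resid.append(float(np.linalg.norm(cpm[:, j] - R @ theta)))
    props = pd.DataFrame(thetas, index=bulk.sample_ids, columns=list(reference.columns))
    return MixingEstimate(
        proportions=props, residual_norm=pd.Series(resid, index=bulk.sample_ids)
    )


def casecontrol_workflow(
    bulk: CountMatrix,
    metadata: pd.DataFrame,
    proportions: pd.DataFrame,
    specificity_sets: dict[str, list[str]] | None = None,
    diagnosis_col: str = "diagnosis",
    extra_numeric: tuple[str, ...] = (),
    net_threshold: float = 0.05,
    pi0_method: str = "smoother",
    norm_factors: np.ndarray | str | None = "tmm",
) -> dict:
    """Diagnosis-contrast pi1 with and without composition covariates.

    The base model is diagnosis (+ any ``extra_numeric`` metadata columns
    such as a GC-content metric, offered to BIC selection alongside the
    estimated cell-type proportion columns). Composition covariates are
    admitted by net-BIC forward selection; the diagnosis contrast is then
    fitted without and with the selected composition columns and pi1 is
    estimated from each p-value vector. With ``specificity_sets`` (cell
    label -> OCR ids) pi1 is additionally reported within each cell type's
    specific OCRs under the composition-adjusted model.

    Counts are TMM-normalized by default (``norm_factors="tmm"``): a planted
    or real differential signal otherwise shifts library sizes and imprints
    a spurious opposite-direction effect on every other OCR through the CPM
    denominator. Pass an explicit factor vector, or None for plain CPM.
    """
    diag = metadata[diagnosis_col].astype(str)
    levels = sorted(diag.unique())
    if len(levels) != 2:
        raise InputError(f"diagnosis must have 2 levels, got {levels}")
    if isinstance(norm_factors, str):
        if norm_factors != "tmm":
            raise InputError(f"unknown normalization {norm_factors!r}")
        from .normalize import promoter_tmm

        norm_factors = promoter_tmm(bulk, np.ones(len(bulk.ocr_ids), dtype=bool))
    norm = log_cpm(bulk, norm_factors)
    Y = norm.logcpm
    d = (diag == levels[1]).astype(float).values
    base = np.column_stack([np.ones(len(d)), d])
    coef_names = ["intercept", f"diagnosis[{levels[1]}]"]

    candidates = pd.DataFrame(index=metadata.index)
    for col in extra_numeric:
        candidates[col] = metadata[col].astype(float).values
    # drop one proportion column: they sum to one and would be collinear
    # with the intercept if all entered jointly
    prop_cols = list(proportions.columns)[:-1]
    for col in prop_cols:
        candidates[f"prop_{col}"] = proportions[col].values

    selected, report = bic_forward_select(
        Y, base, candidates, net_threshold=net_threshold, test_squares=False
    )
    comp_selected = [s for s in selected if s.startswith("prop_")]
    other_selected = [s for s in selected if not s.startswith("prop_")]

    def fit_with(extra_cols: list[str]) -> np.ndarray:
        X = base
        for col in extra_cols:
            v = candidates[col].values.astype(float)[:, None]
            Xc = np.column_stack([X, v])
            if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
                warnings.warn(f"covariate {col} collinear with diagnosis; dropped")
                continue
            X = Xc
        contrast = np.zeros(X.shape[1])
        contrast[1] = 1.0
        res = fit_contrasts(Y, None, X, {"diagnosis": contrast}, ocr_ids=bulk.ocr_ids)
        return res["diagnosis"].table

    tab_without = fit_with(other_selected)
    tab_with = fit_with(other_selected + comp_selected)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pi1_without = estimate_pi0(tab_without["p"].values, method=pi0_method).pi1
        pi1_with = estimate_pi0(tab_with["p"].values, method=pi0_method).pi1
        cell_pi1 = {}
        if specificity_sets:
            for cell, ids in specificity_sets.items():
                ids = [i for i in ids if i in tab_with.index]
                if len(ids) == 0:
                    cell_pi1[cell] = np.nan
                    continue
                cell_pi1[cell] = estimate_pi0(
                    tab_with.loc[ids, "p"].values, method=pi0_method
                ).pi1
    return {
        "pi1_without_composition": pi1_without,
        "pi1_with_composition": pi1_with,
        "pi1_by_cell_specific": cell_pi1,
        "selected_covariates": selected,
        "selection_report": report,
    }
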