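"""Differential accessibility and cell/region specificity sets.

Fits the accessibility model (cell type x region groups + sex + FRiP) with
voom-style precision weights, tests the region-summed pairwise cell
contrasts, and applies the set algebra: an OCR is cell-specific only if
significantly more accessible than in EVERY other cell type; neuronal /
non-neuronal sets are unions of two-way intersections.
"""

import numpy as np

from ocrcell import covariates, differential, normalize, simulate

cfg = simulate.SimulationConfig(n_ocrs=3000, seed=21)
counts, metadata, ocrs, annotation, truth = simulate.simulate_sorted_experiment(cfg)
kept = normalize.filter_low(counts)
counts = counts.subset_ocrs(kept)

spec = covariates.ModelSpec.study_default()
X, coef_names = covariates.build_design(metadata, spec)
print(f"model: {len(spec.group_levels)} groups + sex + FRiP = {spec.df_total} df")

weights, norm = differential.voom_weights(counts, np.ones(len(counts.sample_ids)), X)
contrasts = differential.build_cell_pair_contrasts(coef_names)
results = differential.fit_contrasts(
    norm.logcpm, weights.observation_weights, X,
    {f"{a}|{b}": c for (a, b), c in contrasts.items()}, ocr_ids=counts.ocr_ids,
)
pairwise = {tuple(k.split("|")): v for k, v in results.items()}

cells = differential.cell_specific_sets(pairwise, fdr=0.05)
groups = differential.group_specific_sets(pairwise, fdr=0.05)
print("cell-specific OCRs at FDR 5% (planted truth in parentheses):")
for cell, table in cells.items():
    tp = len(set(table.index) & truth.true_specific_ocrs[cell])
    print(f"  {cell:5s}: {len(table):4d} called, {tp} of "
          f"{len(truth.true_specific_ocrs[cell])} planted recovered")
print(f"Neuron set: {len(groups['Neuron'])}, nonNeuron set: {len(groups['nonNeuron'])} "
      "(cell-specific sets are subsets of their group set)")

# regional specificity within GLU, FDR applied over GLU-called OCRs only
region_contrasts = differential.build_region_contrasts(coef_names, "GLU")
region_res = differential.fit_contrasts(
    norm.logcpm, weights.observation_weights, X, region_contrasts,
    ocr_ids=counts.ocr_ids,
)
mask = np.ones(len(counts.ocr_ids), dtype=bool)
region_sets = differential.region_specific_sets(region_res, mask, fdr=0.05)
planted_acc = truth.true_region_ocrs[("GLU", "ACC")]
found = len(set(region_sets["ACC"].index) & planted_acc)
print(f"GLU regional OCRs: ACC {len(region_sets['ACC'])} "
      f"({found}/{len(planted_acc)} planted ACC-up recovered), "
      f"DLPFC {len(region_sets['DLPFC'])}, PVC {len(region_sets['PVC'])}")

# residualize sex + FRiP out, keeping cell/region structure
adjusted = differential.residualize(norm.logcpm, X, coef_names, ["sex", "frip"])
beta2, *_ = np.linalg.lstsq(X, adjusted.T, rcond=None)
print(f"after residualization, median FRiP coefficient = "
      f"{np.median(beta2[coef_names.index('frip')]):.2e} (effect removed)")
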