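"""Deconvolve bulk chromatin samples and run the case-control pi1 workflow.

Cell-type proportions of bulk samples are estimated by a simplex-
constrained linear mixing model on marker-OCR CPM. A case-control cohort
with a disease effect planted on GLU-linked OCRs is then analyzed twice --
with and without the estimated composition covariates (admitted by net-BIC
selection) -- and the diagnosis signal is quantified with pi1, overall and
within each cell type's specific OCRs.
"""

import warnings

import numpy as np

from ocrcell import deconvolve, simulate

ref, markers = simulate.simulate_celltype_profiles(
    n_ocrs=2000, n_markers_per_cell=200, seed=11
)
refcpm = ref / ref.sum(0) * 1e6
panel = deconvolve.MarkerPanel(markers)
print(f"marker panel: {({c: len(v) for c, v in markers.items()})}")

bulk, meta, truth = simulate.simulate_bulk_mixtures(
    ref, 20, np.ones(4), depth=1_000_000, seed=12
)
est = deconvolve.estimate_proportions(bulk, refcpm.loc[panel.all_markers], panel)
rmse = np.sqrt(np.mean((est.proportions.values - truth.true_proportions.values) ** 2))
print(f"proportion recovery on 20 Dirichlet mixtures: RMSE = {rmse:.3f}")
print("first three samples (estimated | true GLU fraction):")
for sid in bulk.sample_ids[:3]:
    print(f"  {sid}: {est.proportions.loc[sid, 'GLU']:.3f} | "
          f"{truth.true_proportions.loc[sid, 'GLU']:.3f}")

rng = np.random.default_rng(55)
half = rng.dirichlet(np.ones(4), size=20)
theta = np.vstack([half, half])  # cases and controls share compositions
bulk_cc, meta_cc, _ = simulate.simulate_bulk_mixtures(
    ref, 40, np.ones(4), case_effect=(markers["GLU"][:100], 1.0),
    depth=1_000_000, nb_dispersion=0.05, seed=56, proportions=theta,
)
props = deconvolve.estimate_proportions(
    bulk_cc, refcpm.loc[panel.all_markers], panel
).proportions
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    out = deconvolve.casecontrol_workflow(bulk_cc, meta_cc, props, markers)
print(f"\ncovariates selected by net-BIC: {out['selected_covariates']}")
print(f"diagnosis pi1 without composition: {out['pi1_without_composition']:.3f}")
print(f"diagnosis pi1 with composition:    {out['pi1_with_composition']:.3f}")
print("pi1 within cell-specific OCRs:",
      {c: round(v, 3) for c, v in out["pi1_by_cell_specific"].items()})
print("(the GLU-restricted pi1 is largest: the planted disease effect "
      "sits on GLU-linked OCRs)")
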