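import numpy as np
import pytest

from ocrcell import covariates, differential, normalize, simulate


@pytest.fixture(scope="session")
def sorted_experiment():
    """A small sorted-nuclei experiment shared across tests (read-only)."""
    cfg = simulate.SimulationConfig(n_ocrs=2000, seed=101)
    return simulate.simulate_sorted_experiment(cfg)


@pytest.fixture(scope="session")
def fitted_pipeline(sorted_experiment):
    """Counts -> filter -> TMM -> voom -> pairwise cell contrasts."""
    cm, meta, ocrs, ann, truth = sorted_experiment
    kept = normalize.filter_low(cm)
    cm2 = cm.subset_ocrs(kept)
    spec = covariates.ModelSpec.study_default()
    X, names = covariates.build_design(meta, spec)
    weights, norm = differential.voom_weights(cm2, np.ones(len(cm2.sample_ids)), X)
    pair_contrasts = differential.build_cell_pair_contrasts(names)
    res = differential.fit_contrasts(
        norm.logcpm,
        weights.observation_weights,
        X,
        {f"{a}|{b}": c for (a, b), c in pair_contrasts.items()},
        ocr_ids=cm2.ocr_ids,
    )
    pairwise = {tuple(k.split("|")): v for k, v in res.items()}
    return {
        "counts": cm2,
        "metadata": meta,
        "truth": truth,
        "design": X,
        "coef_names": names,
        "weights": weights,
        "norm": norm,
        "pairwise": pairwise,
    }
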