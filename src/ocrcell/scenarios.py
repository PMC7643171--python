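"""End-to-end study scenarios exercising the pipeline on synthetic data.

Each function builds its inputs with the synthetic-data generator, runs the
relevant pipeline stages, and returns the measured quantities (recovery
errors, calibration statistics, selection rates). These are the scenarios
the package's acceptance checks and examples run; problem sizes are chosen
to mirror the sorted-nuclei study design at desk scale (a few thousand OCRs,
4 samples per cell-type-by-region group, per-sample depth around one
million fragments in OCRs).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import covariates, deconvolve, differential, normalize, overlap, pi1, simulate
from .footprints import BindingSite, motif_enrichment, site_gene_weight
from .intervals import GenomicInterval, OCRSet

CELLS = ("GLU", "GABA", "OLIG", "MGAS")
REGIONS = ("ACC", "DLPFC", "PVC")
PAIRS = [(a, b) for i, a in enumerate(CELLS) for b in CELLS[i + 1:]]


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 10_007 + k) % (2**31 - 1)


def run_sorted_pipeline(config: simulate.SimulationConfig):
    """Simulate, filter, normalize (unit factors), voom, pairwise contrasts."""
    cm, meta, ocrs, ann, truth = simulate.simulate_sorted_experiment(config)
    kept = normalize.filter_low(cm)
    cm2 = cm.subset_ocrs(kept)
    X, names = covariates.build_design(meta, covariates.ModelSpec.study_default())
    weights, norm = differential.voom_weights(cm2, np.ones(len(cm2.sample_ids)), X)
    cons = differential.build_cell_pair_contrasts(names)
    res = differential.fit_contrasts(
        norm.logcpm, weights.observation_weights, X,
        {f"{a}|{b}": c for (a, b), c in cons.items()}, ocr_ids=cm2.ocr_ids,
    )
    pairwise = {tuple(k.split("|")): v for k, v in res.items()}
    return cm2, meta, truth, X, names, weights, norm, pairwise


def design_combinatorics(seed: int) -> dict:
    """Group structure of the design: 12 groups, 66 comparisons, 14 df."""
    spec = covariates.ModelSpec.study_default()
    cfg = simulate.SimulationConfig(
        n_ocrs=400, n_specific_per_cell=10, n_region_specific=2, seed=_sub_seed(seed, 1)
    )
    cm2, meta, truth, X, names, weights, norm, _ = run_sorted_pipeline(cfg)
    groups = list(spec.group_levels)
    mat = pi1.pairwise_pi1(
        norm.logcpm, weights.observation_weights, X, names, groups
    )
    n_pairs = int(mat.notna().sum().sum() // 2)
    return {
        "n_groups": len(groups),
        "n_pairwise_comparisons": n_pairs,
        "model_df": spec.df_total,
    }


def set_algebra_agreement() -> dict:
    """Agreement of the specificity set algebra with brute-force evaluation
    over every significance pattern of the six pairwise comparisons."""
    patterns = [
        dict(zip(PAIRS, states))
        for states in itertools.product((-1, 0, 1), repeat=6)
    ]
    ids = [f"P{i}" for i in range(len(patterns))]
    results = {}
    for a, b in PAIRS:
        fc = [1.0 if pat[(a, b)] >= 0 else -1.0 for pat in patterns]
        fdr = [0.001 if pat[(a, b)] != 0 else 0.9 for pat in patterns]
        t = pd.DataFrame({"log2fc": fc, "t": fc, "p": fdr, "fdr": fdr}, index=ids)
        results[(a, b)] = differential.DifferentialResult(t, f"{a}|{b}")
    cells = differential.cell_specific_sets(results)
    groups = differential.group_specific_sets(results)

    def sig(pat, x, y):
        return pat[(x, y)] == 1 if (x, y) in pat else pat[(y, x)] == -1

    n_checked = n_agree = 0
    for i, pat in enumerate(patterns):
        for c in CELLS:
            expected = all(sig(pat, c, o) for o in CELLS if o != c)
            n_checked += 1
            n_agree += (ids[i] in cells[c].index) == expected
        neuron = (sig(pat, "GLU", "OLIG") and sig(pat, "GLU", "MGAS")) or (
            sig(pat, "GABA", "OLIG") and sig(pat, "GABA", "MGAS"))
        nonneuron = (sig(pat, "OLIG", "GLU") and sig(pat, "OLIG", "GABA")) or (
            sig(pat, "MGAS", "GLU") and sig(pat, "MGAS", "GABA"))
        n_checked += 2
        n_agree += (ids[i] in groups["Neuron"].index) == neuron
        n_agree += (ids[i] in groups["nonNeuron"].index) == nonneuron
    return {
        "n_patterns": len(patterns),
        "agreement_pct": 100.0 * n_agree / n_checked,
    }


def tmm_recovery(seed: int) -> dict:
    """Promoter-anchored TMM factor recovery and non-promoter invariance.

    5,000 OCRs, 12 samples (one per cell-type-by-region group), uniform
    depth 1e6. Recovery compares estimated factors to the recorded truth;
    invariance compares the promoter-anchored effective library sizes with
    and without the planted cell-specific (non-promoter) OCR rows, up to a
    global constant.
    """
    cfg = simulate.SimulationConfig(
        n_ocrs=5000, n_samples_per_group=1,
        library_size_range=(1_000_000, 1_000_000), seed=_sub_seed(seed, 3),
    )
    cm, meta, ocrs, ann, truth = simulate.simulate_sorted_experiment(cfg)
    prom = np.zeros(len(ocrs), dtype=bool)
    for _, row in ann.tss.iterrows():
        probe = GenomicInterval(row["chrom"], int(row["pos"]), int(row["pos"]) + 1)
        prom[ocrs.overlapping_indices(probe)] = True
    factors = normalize.promoter_tmm(cm, prom)
    truth_f = truth.true_norm_factors.loc[cm.sample_ids].values
    ratio = factors / truth_f
    ratio = ratio / np.exp(np.mean(np.log(ratio)))
    max_recovery_err = float(np.abs(ratio - 1).max())

    specific = set().union(*truth.true_specific_ocrs.values())
    keep = np.array([oid not in specific for oid in cm.ocr_ids])
    cm_wo = cm.subset_ocrs(np.flatnonzero(keep))
    f_wo = normalize.promoter_tmm(cm_wo, prom[keep])
    eff_with = cm.library_sizes * factors
    eff_wo = cm_wo.library_sizes * f_wo
    r = eff_with / eff_wo
    r = r / np.exp(np.mean(np.log(r)))
    invariance_err = float(np.abs(r - 1).max())
    return {
        "tmm_max_recovery_error_pct": 100.0 * max_recovery_err,
        "tmm_invariance_max_shift_pct": 100.0 * invariance_err,
    }


def differential_calibration(seed: int) -> dict:
    """Null p-value uniformity, null FDR discoveries, and log2FC recovery.

    5,000 OCRs, 48 samples (4 per group), uniform depth 1e6, planted
    specificity effects of log2FC 2.
    """
    cfg = simulate.SimulationConfig(
        n_ocrs=5000, library_size_range=(1_000_000, 1_000_000),
        seed=_sub_seed(seed, 4),
    )
    cm2, meta, truth, X, names, weights, norm, pairwise = run_sorted_pipeline(cfg)
    tab = pairwise[("GLU", "GABA")].table
    planted = set().union(
        *truth.true_specific_ocrs.values(),
        *truth.true_region_ocrs.values(),
        set(truth.planted_covariate_effects["sex"]),
    )
    null_ids = [o for o in tab.index if o not in planted]
    ks_p = float(stats.kstest(tab.loc[null_ids, "p"].values, "uniform").pvalue)
    null_fdr_rate = float(np.mean(tab.loc[null_ids, "fdr"] < 0.05))
    errs = []
    for pair in (("GLU", "GABA"), ("OLIG", "MGAS")):
        t = pairwise[pair].table
        up = [o for o in truth.true_specific_ocrs[pair[0]] if o in t.index]
        down = [o for o in truth.true_specific_ocrs[pair[1]] if o in t.index]
        errs.append(t.loc[up, "log2fc"].values - cfg.effect_log2fc)
        errs.append(t.loc[down, "log2fc"].values + cfg.effect_log2fc)
    errs = np.concatenate(errs)
    return {
        "null_ks_p": ks_p,
        "null_fdr_discovery_pct": 100.0 * null_fdr_rate,
        "log2fc_within_0p2_pct": 100.0 * float(np.mean(np.abs(errs) <= 0.2)),
    }


def pi1_calibration(seed: int, n: int = 10_000, n_seeds: int = 20) -> dict:
    """Seed-averaged pi1 estimation error over a pi0 grid."""
    grid = np.round(np.arange(0.1, 1.01, 0.1), 1)
    worst = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pi0 in grid:
            ests = [
                pi1.estimate_pi0(
                    simulate.simulate_pvalues(
                        n, float(pi0), 0.05, seed=_sub_seed(seed, 50 + int(pi0 * 10) * 100 + s)
                    )
                ).pi1
                for s in range(n_seeds)
            ]
            worst = max(worst, abs(float(np.mean(ests)) - (1.0 - float(pi0))))
    return {"pi1_max_mean_abs_error": worst}


def bic_selection_rates(seed: int, n_seeds: int = 100) -> dict:
    """Net-BIC selection of a planted FRiP-like covariate vs pure noise.

    The planted covariate carries a strong effect on 50% of OCRs; two pure
    noise candidates compete. Reports how often the planted covariate is
    selected first and how often any noise candidate is ever selected.
    """
    first = noise_any = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 600 + s))
        G, n = 600, 48
        cov = rng.normal(0, 1, n)
        Y = rng.normal(0, 1, (G, n))
        hit = rng.choice(G, G // 2, replace=False)
        Y[hit] += np.outer(rng.normal(1.0, 0.2, len(hit)), cov)
        cands = pd.DataFrame(
            {"planted": cov, "noise_a": rng.normal(size=n),
             "noise_b": rng.normal(size=n)}
        )
        selected, _ = covariates.bic_forward_select(
            Y, np.ones((n, 1)), cands, test_squares=False
        )
        first += bool(selected and selected[0] == "planted")
        noise_any += any(c.startswith("noise") for c in selected)
    return {
        "bic_planted_selected_first_pct": 100.0 * first / n_seeds,
        "bic_noise_selected_pct": 100.0 * noise_any / n_seeds,
    }


def deconvolution_recovery(seed: int, n_mixtures: int = 50) -> dict:
    """Proportion RMSE over Dirichlet mixtures and pure-profile recovery."""
    ref, markers = simulate.simulate_celltype_profiles(
        n_ocrs=3000, n_markers_per_cell=300, seed=_sub_seed(seed, 7)
    )
    refcpm = ref / ref.sum(0) * 1e6
    panel = deconvolve.MarkerPanel(markers)
    bulk, _, truth = simulate.simulate_bulk_mixtures(
        ref, n_mixtures, np.ones(4), depth=1_000_000, seed=_sub_seed(seed, 8)
    )
    est = deconvolve.estimate_proportions(bulk, refcpm.loc[panel.all_markers], panel)
    rmse = float(np.sqrt(np.mean(
        (est.proportions.values - truth.true_proportions.values) ** 2
    )))
    pure = normalize.CountMatrix(
        np.round(refcpm.values).astype(int), list(ref.index), list(ref.columns)
    )
    est_pure = deconvolve.estimate_proportions(
        pure, refcpm.loc[panel.all_markers], panel
    )
    return {
        "deconv_rmse": rmse,
        "deconv_pure_recovery_min": float(np.diag(est_pure.proportions.values).min()),
    }


def casecontrol_power(seed: int, n_seeds: int = 50) -> dict:
    """pi1 gain from composition adjustment and cell-restricted ordering.

    Bulk cohorts of 40 samples with wide, diagnosis-matched composition
    variation and a diagnosis effect planted on GLU-marker OCRs; counts at
    homogenate-typical dispersion 0.05, depth 1e6.
    """
    ref, markers = simulate.simulate_celltype_profiles(
        n_ocrs=2000, n_markers_per_cell=200, seed=_sub_seed(seed, 9)
    )
    refcpm = ref / ref.sum(0) * 1e6
    panel = deconvolve.MarkerPanel(markers)
    gain = glu_top = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 900 + s))
        half = rng.dirichlet(np.ones(4), size=20)
        theta = np.vstack([half, half])
        bulk, meta, _ = simulate.simulate_bulk_mixtures(
            ref, 40, np.ones(4), case_effect=(markers["GLU"][:100], 1.0),
            depth=1_000_000, nb_dispersion=0.05,
            seed=_sub_seed(seed, 950 + s), proportions=theta,
        )
        props = deconvolve.estimate_proportions(
            bulk, refcpm.loc[panel.all_markers], panel
        ).proportions
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = deconvolve.casecontrol_workflow(bulk, meta, props, markers)
        gain += out["pi1_with_composition"] >= out["pi1_without_composition"]
        by_cell = out["pi1_by_cell_specific"]
        glu_top += by_cell["GLU"] == max(by_cell.values())
    return {
        "casecontrol_pi1_gain_pct": 100.0 * gain / n_seeds,
        "casecontrol_glu_top_pct": 100.0 * glu_top / n_seeds,
    }


def exact_statistics() -> dict:
    """Closed-form checks of the exact-statistics operations.

    Returns the computed values together with the largest absolute deviation
    from independently derived closed forms.
    """
    devs = []
    # regulatory-domain binomial enrichment: Bin(4, 0.25) upper tail at 2
    domains = [
        overlap.RegulatoryDomain(
            f"g{i}", GenomicInterval("chr1", i * 1000, (i + 1) * 1000),
            GenomicInterval("chr1", i * 1000 + 400, i * 1000 + 600),
        )
        for i in range(4)
    ]
    ocrs = OCRSet([
        GenomicInterval("chr1", 100, 150), GenomicInterval("chr1", 300, 350),
        GenomicInterval("chr1", 1100, 1150), GenomicInterval("chr1", 2100, 2150),
    ])
    fold, great_p = overlap.great_enrichment(ocrs, domains, {"g0"})
    closed = float(sum(stats.binom.pmf(k, 4, 0.25) for k in (2, 3, 4)))
    devs.append(abs(great_p - closed))

    # Fisher exact vs the hypergeometric tail oracle
    table = [[10, 100], [5, 900]]
    res = overlap.eqtl_enrichment(
        OCRSet([GenomicInterval("chr1", 0, 100)]),
        pd.DataFrame({
            "chrom": ["chr1"] * 1015,
            "pos": [50] * 110 + list(range(10_000, 10_905)),
            "credible": [1] * 10 + [0] * 100 + [1] * 5 + [0] * 900,
        }),
    )
    _, fisher_oracle = stats.fisher_exact(table, alternative="two-sided")
    devs.append(abs(res["fisher_p"] - float(fisher_oracle)))

    # base-pair Jaccard of [0,10) vs [5,15): 5/15
    jac = overlap.jaccard_bp(
        [GenomicInterval("chr1", 0, 10)], [GenomicInterval("chr1", 5, 15)]
    )
    devs.append(abs(jac - 5 / 15))

    # exponential decay weight at one decay scale: e^-1
    w = site_gene_weight(
        BindingSite("m", GenomicInterval("chr1", 9995, 10005), 1.0), [0], 10_000
    )
    devs.append(abs(w - float(np.exp(-1.0))))

    # coverage-aware binomial motif enrichment: all 20 bound sites in a
    # target covering half the bp -> p = 0.5^20
    target = OCRSet([GenomicInterval("chr1", 0, 1000)])
    background = OCRSet([GenomicInterval("chr1", 10_000, 11_000)])
    sites = [
        BindingSite("m", GenomicInterval("chr1", 10 * i, 10 * i + 8), 0.95)
        for i in range(20)
    ]
    out = motif_enrichment(sites, target, background)
    devs.append(abs(out.loc["m", "p"] - 0.5**20))

    return {
        "exact_stats_max_abs_dev": float(max(devs)),
        "great_binomial_p": float(great_p),
        "jaccard_example": float(jac),
        "decay_weight_at_scale": float(w),
        "motif_binomial_p": float(out.loc["m", "p"]),
    }
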