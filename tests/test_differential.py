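"""Voom weights, moderated contrasts, and the specificity set algebra."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest

from ocrcell.differential import (
    DifferentialResult,
    build_cell_pair_contrasts,
    build_region_contrasts,
    cell_specific_sets,
    fit_contrasts,
    group_specific_sets,
    pair_result,
    region_specific_sets,
    residualize,
    voom_weights,
)
from ocrcell.exceptions import InputError
from ocrcell.normalize import CountMatrix

CELLS = ("GLU", "GABA", "OLIG", "MGAS")
PAIRS = [(a, b) for i, a in enumerate(CELLS) for b in CELLS[i + 1:]]


class TestVoomWeights:
    def test_homoskedastic_data_gives_flat_weights(self):
        rng = np.random.default_rng(0)
        n, G = 24, 800
        lib = 1_000_000
        # equal-variance Gaussian log-CPM has no mean-variance trend
        counts = rng.poisson(np.full((G, n), lib / G)).astype(int)
        cm = CountMatrix(counts, [f"O{i}" for i in range(G)], [f"S{j}" for j in range(n)])
        X = np.ones((n, 1))
        w, _ = voom_weights(cm, np.ones(n), X)
        cv = w.observation_weights.std() / w.observation_weights.mean()
        assert cv < 0.2

    def test_weights_increase_with_abundance_for_nb_counts(self):
        rng = np.random.default_rng(1)
        n, G = 24, 1500
        mu = np.exp(rng.normal(3, 1.5, size=G))
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(G, n))
        cm = CountMatrix(counts, [f"O{i}" for i in range(G)], [f"S{j}" for j in range(n)])
        w, _ = voom_weights(cm, np.ones(n), np.ones((n, 1)))
        med = np.median(w.observation_weights, axis=1)
        order = np.argsort(mu)
        low, high = med[order[: G // 10]], med[order[-G // 10:]]
        assert np.median(high) > np.median(low)
        assert (w.observation_weights > 0).all()

    def test_insufficient_residual_df_rejected(self):
        cm = CountMatrix(np.ones((10, 3), dtype=int), list("abcdefghij"), list("xyz"))
        with pytest.raises(InputError, match="residual"):
            voom_weights(cm, np.ones(3), np.eye(3)[:, :2])


class TestFitContrasts:
    def test_matches_limma_ebayes_oracle(self, tmp_path):
        """Independent oracle: limma lmFit + eBayes on the same matrix."""
        rng = np.random.default_rng(7)
        G, n = 300, 10
        X = np.column_stack([np.ones(n), np.repeat([0, 1], 5)])
        beta = np.column_stack([rng.normal(5, 1, G), rng.normal(0, 0.5, G)])
        Y = beta @ X.T + rng.normal(0, rng.gamma(3, 0.1, G)[:, None] ** 0.5, (G, n))
        ypath = tmp_path / "y.tsv"
        opath = tmp_path / "limma.tsv"
        pd.DataFrame(Y).to_csv(ypath, sep="\t")
        script = (
            'suppressMessages(library(limma));'
            f'y <- as.matrix(read.delim("{ypath}", row.names=1));'
            'design <- cbind(1, rep(c(0,1), each=5));'
            'fit <- eBayes(lmFit(y, design));'
            'tt <- topTable(fit, coef=2, number=Inf, sort.by="none");'
            f'write.table(tt[,c("logFC","t","P.Value")], "{opath}", sep="\\t", quote=FALSE)'
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        lt = pd.read_csv(opath, sep="\t")
        tab = fit_contrasts(Y, None, X, {"c": np.array([0.0, 1.0])})["c"].table
        assert np.abs(tab["log2fc"].values - lt["logFC"].values).max() < 1e-8
        assert np.abs(tab["t"].values - lt["t"].values).max() < 1e-8
        assert np.abs(
            np.log(tab["p"].values) - np.log(lt["P.Value"].values)
        ).max() < 1e-8

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        G, n = 5000, 16
        Y = rng.normal(0, 1, (G, n))
        X = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
        tab = fit_contrasts(Y, None, X, {"c": np.array([0.0, 1.0])})["c"].table
        from scipy import stats

        assert stats.kstest(tab["p"].values, "uniform").pvalue > 0.01

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(50, 12))
        X = np.column_stack([np.repeat([1, 0], 6), np.repeat([0, 1], 6)])
        res = fit_contrasts(
            Y, None, X, {"ab": np.array([1.0, -1.0]), "ba": np.array([-1.0, 1.0])}
        )
        assert np.allclose(
            res["ab"].table["log2fc"], -res["ba"].table["log2fc"]
        )
        assert np.allclose(res["ab"].table["p"], res["ba"].table["p"])

    def test_zero_contrast_rejected(self):
        Y = np.random.default_rng(0).normal(size=(10, 6))
        X = np.ones((6, 1))
        with pytest.raises(InputError, match="zero"):
            fit_contrasts(Y, None, X, {"z": np.zeros(1)})

    def test_wrong_length_contrast_rejected(self):
        Y = np.random.default_rng(0).normal(size=(10, 6))
        with pytest.raises(InputError, match="length"):
            fit_contrasts(Y, None, np.ones((6, 1)), {"c": np.ones(3)})


def _pattern_results(patterns):
    """Encode significance patterns as pairwise DifferentialResult tables.

    ``patterns`` is a list of dicts mapping each ordered pair to a state in
    {+1: first cell significantly higher, -1: second higher, 0: neither}.
    """
    ids = [f"P{i}" for i in range(len(patterns))]
    results = {}
    for a, b in PAIRS:
        fc, fdr = [], []
        for pat in patterns:
            s = pat[(a, b)]
            fc.append(1.0 if s >= 0 else -1.0)
            fdr.append(0.001 if s != 0 else 0.9)
        t = pd.DataFrame(
            {"log2fc": fc, "t": fc, "p": fdr, "fdr": fdr}, index=ids
        )
        results[(a, b)] = DifferentialResult(t, contrast_id=f"{a}|{b}")
    return results, ids


def _brute_force_sets(pat):
    """Direct evaluation of the displayed set definitions for one pattern."""
    def sig(x, y):
        if (x, y) in pat:
            return pat[(x, y)] == 1
        return pat[(y, x)] == -1

    cell = {
        c: all(sig(c, o) for o in CELLS if o != c) for c in CELLS
    }
    neuron = (sig("GLU", "OLIG") and sig("GLU", "MGAS")) or (
        sig("GABA", "OLIG") and sig("GABA", "MGAS")
    )
    non_neuron = (sig("OLIG", "GLU") and sig("OLIG", "GABA")) or (
        sig("MGAS", "GLU") and sig("MGAS", "GABA")
    )
    return cell, neuron, non_neuron


class TestSpecificitySetAlgebra:
    def test_exhaustive_patterns_match_brute_force(self):
        """All 3^6 significance patterns of the six pairwise comparisons."""
        patterns = [
            dict(zip(PAIRS, states))
            for states in itertools.product((-1, 0, 1), repeat=6)
        ]
        results, ids = _pattern_results(patterns)
        cells = cell_specific_sets(results)
        groups = group_specific_sets(results)
        for i, pat in enumerate(patterns):
            expected_cell, expected_neuron, expected_non = _brute_force_sets(pat)
            for c in CELLS:
                assert (ids[i] in cells[c].index) == expected_cell[c], (i, c)
            assert (ids[i] in groups["Neuron"].index) == expected_neuron, i
            assert (ids[i] in groups["nonNeuron"].index) == expected_non, i

    def test_cell_sets_pairwise_disjoint(self):
        patterns = [
            dict(zip(PAIRS, states))
            for states in itertools.product((-1, 0, 1), repeat=6)
        ]
        results, _ = _pattern_results(patterns)
        cells = cell_specific_sets(results)
        for a, b in itertools.combinations(CELLS, 2):
            assert not (set(cells[a].index) & set(cells[b].index))

    def test_cell_specific_implies_group_membership(self):
        patterns = [
            dict(zip(PAIRS, states))
            for states in itertools.product((-1, 0, 1), repeat=6)
        ]
        results, _ = _pattern_results(patterns)
        cells = cell_specific_sets(results)
        groups = group_specific_sets(results)
        assert set(cells["GLU"].index) <= set(groups["Neuron"].index)
        assert set(cells["GABA"].index) <= set(groups["Neuron"].index)
        assert set(cells["OLIG"].index) <= set(groups["nonNeuron"].index)
        assert set(cells["MGAS"].index) <= set(groups["nonNeuron"].index)

    def test_shared_neuronal_ocr_in_neuron_set_but_not_cell_sets(self):
        # high in GLU and GABA, low in OLIG/MGAS: Neuronal, not GLU-specific
        pat = {p: 0 for p in PAIRS}
        pat[("GLU", "OLIG")] = pat[("GLU", "MGAS")] = 1
        pat[("GABA", "OLIG")] = pat[("GABA", "MGAS")] = 1
        results, ids = _pattern_results([pat])
        cells = cell_specific_sets(results)
        groups = group_specific_sets(results)
        assert all(ids[0] not in cells[c].index for c in CELLS)
        assert ids[0] in groups["Neuron"].index

    def test_least_significant_statistics_reported(self):
        ids = ["X"]
        results = {}
        stats_by_pair = {
            ("GLU", "GABA"): (2.0, 0.001),
            ("GLU", "OLIG"): (1.5, 0.04),
            ("GLU", "MGAS"): (3.0, 0.0001),
        }
        for a, b in PAIRS:
            fc, fdr = stats_by_pair.get((a, b), (-1.0, 0.9))
            t = pd.DataFrame(
                {"log2fc": [fc], "t": [fc], "p": [fdr], "fdr": [fdr]}, index=ids
            )
            results[(a, b)] = DifferentialResult(t, f"{a}|{b}")
        out = cell_specific_sets(results)
        assert out["GLU"].loc["X", "p"] == 0.04  # worst of the three
        assert out["GLU"].loc["X", "log2fc"] == 1.5

    def test_missing_contrast_raises(self):
        results, _ = _pattern_results([{p: 1 for p in PAIRS}])
        del results[("GLU", "GABA")]
        with pytest.raises(InputError, match="missing"):
            pair_result(results, "GLU", "GABA")


class TestRegionSets:
    def test_masked_ocrs_only_and_local_fdr(self):
        rng = np.random.default_rng(5)
        G = 200
        p = rng.uniform(0.2, 1.0, G)
        fc = rng.normal(0, 1, G)
        p[0], fc[0] = 1e-12, 3.0   # inside mask
        p[1], fc[1] = 1e-12, 3.0   # outside mask: must never be reported
        ids = [f"O{i}" for i in range(G)]
        from statsmodels.stats.multitest import multipletests

        tab = pd.DataFrame(
            {"log2fc": fc, "t": fc, "p": p,
             "fdr": multipletests(p, method="fdr_bh")[1]},
            index=ids,
        )
        res = {
            "ACC": DifferentialResult(tab, "ACC"),
            "DLPFC": DifferentialResult(tab, "DLPFC"),
        }
        mask = np.ones(G, dtype=bool)
        mask[1] = False
        out = region_specific_sets(res, mask)
        assert "O0" in out["ACC"].index
        assert "O1" not in out["ACC"].index

    def test_requires_two_regions(self):
        tab = pd.DataFrame(
            {"log2fc": [1.0], "t": [1.0], "p": [0.5], "fdr": [0.5]}, index=["a"]
        )
        with pytest.raises(InputError):
            region_specific_sets({"ACC": DifferentialResult(tab, "ACC")}, np.array([True]))


class TestResidualize:
    def _setup(self):
        rng = np.random.default_rng(6)
        n, G = 48, 200
        group = np.repeat(np.arange(4), 12)
        sex = np.tile([0, 1], 24)
        frip = rng.uniform(0.2, 0.6, n)
        X = np.column_stack(
            [np.eye(4)[group], sex, frip]
        )
        names = [f"group[g{i}]" for i in range(4)] + ["sex[F]", "frip"]
        beta = np.column_stack(
            [rng.normal(5, 1, (G, 4)), rng.normal(1, 0.2, (G, 1)),
             rng.normal(2, 0.5, (G, 1))]
        )
        Y = beta @ X.T + rng.normal(0, 0.3, (G, n))
        return Y, X, names, frip, group

    def test_removed_covariate_has_zero_post_hoc_effect(self):
        Y, X, names, frip, group = self._setup()
        adj = residualize(Y, X, names, ["sex", "frip"])
        # regress each adjusted row on the full design again
        beta2, *_ = np.linalg.lstsq(X, adj.T, rcond=None)
        assert np.abs(np.median(beta2[5])) < 1e-8  # frip coefficient

    def test_idempotent(self):
        Y, X, names, *_ = self._setup()
        a1 = residualize(Y, X, names, ["frip"])
        a2 = residualize(a1, X, names, ["frip"])
        assert np.allclose(a1, a2, atol=1e-10)

    def test_group_differences_preserved(self):
        Y, X, names, frip, group = self._setup()
        adj = residualize(Y, X, names, ["sex", "frip"])
        raw_diff = Y[:, group == 0].mean(1) - Y[:, group == 1].mean(1)
        adj_diff = adj[:, group == 0].mean(1) - adj[:, group == 1].mean(1)
        # nuisance removal changes group means only via the nuisance imbalance
        assert np.corrcoef(raw_diff, adj_diff)[0, 1] > 0.95

    def test_unknown_label_rejected(self):
        Y, X, names, *_ = self._setup()
        with pytest.raises(InputError, match="unknown"):
            residualize(Y, X, names, ["batch"])


class TestContrastBuilders:
    def test_region_summed_cell_contrast(self):
        names = [f"group[{c}_{r}]" for c in CELLS for r in ("ACC", "DLPFC", "PVC")]
        cons = build_cell_pair_contrasts(names)
        assert len(cons) == 6
        c = cons[("GLU", "GABA")]
        assert c[names.index("group[GLU_ACC]")] == pytest.approx(1 / 3)
        assert c[names.index("group[GABA_PVC]")] == pytest.approx(-1 / 3)
        assert c.sum() == pytest.approx(0.0)

    def test_region_vs_mean_of_others(self):
        names = [f"group[GLU_{r}]" for r in ("ACC", "DLPFC", "PVC")]
        cons = build_region_contrasts(names, "GLU")
        c = cons["ACC"]
        assert c[0] == 1.0 and c[1] == pytest.approx(-0.5) and c[2] == pytest.approx(-0.5)
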