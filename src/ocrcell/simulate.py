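"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the sorted-nuclei study design: negative-binomial
fragment counts over OCRs for 4 cell types x 3 brain regions, planted
cell-specific and region-specific OCRs, a FRiP-like signal-allocation
covariate (higher FRiP shifts reads from background regions into signal
OCRs), sex effects on a few sex-chromosome OCRs, bulk mixtures with known
cell proportions and an optional planted case-control effect, and
footprinted binding sites with binding probabilities. Every planted
parameter is recorded in :class:`SyntheticTruth` so each downstream stage
can be tested for recovery without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .intervals import GenomicInterval, OCRSet
from .normalize import CountMatrix
from .footprints import BindingSite
from .overlap import GeneAnnotation

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_sorted_experiment",
    "simulate_bulk_mixtures",
    "simulate_footprints",
    "simulate_pvalues",
    "save_simulation",
]

CELL_TYPES = ("GLU", "GABA", "OLIG", "MGAS")
REGIONS = ("ACC", "DLPFC", "PVC")


@dataclass
class SimulationConfig:
    """Parameters of the sorted-nuclei experiment generator.

    Defaults reflect the study design being emulated: 4 cell types x 3
    regions with 4 samples per group, ~30% promoter OCRs, planted
    specificity effects of log2FC 2, and negative-binomial overdispersion
    at the level of uniformly processed same-donor sorted-nuclei
    replicates (biological CV 0.1).
    """

    n_ocrs: int = 5000
    n_samples_per_group: int = 4
    cell_types: tuple[str, ...] = CELL_TYPES
    regions: tuple[str, ...] = REGIONS
    frac_promoter: float = 0.3
    n_specific_per_cell: int = 100
    n_region_specific: int = 20
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.01
    library_size_range: tuple[int, int] = (500_000, 1_500_000)
    frip_range: tuple[float, float] = (0.2, 0.6)
    frac_background: float = 0.15
    n_sex_ocrs: int = 5
    sex_log2fc: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_ocrs <= 0 or self.n_samples_per_group <= 0:
            raise ConfigurationError("counts must be positive")
        if not (0.0 <= self.frac_promoter <= 1.0):
            raise ConfigurationError("frac_promoter must be in [0,1]")
        if not (0.0 <= self.frac_background <= 1.0):
            raise ConfigurationError("frac_background must be in [0,1]")
        if self.n_specific_per_cell < 0 or self.n_region_specific < 0:
            raise ConfigurationError("planted OCR counts must be >= 0")
        if not np.isfinite(self.effect_log2fc):
            raise ConfigurationError("effect_log2fc must be finite")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid library_size_range")
        flo, fhi = self.frip_range
        if not (0.0 < flo <= fhi < 1.0):
            raise ConfigurationError("frip_range must lie inside (0,1)")
        n_cells, n_regions = len(self.cell_types), len(self.regions)
        planted = (
            n_cells * self.n_specific_per_cell
            + n_cells * n_regions * self.n_region_specific
        )
        n_free = self.n_ocrs - int(round(self.frac_promoter * self.n_ocrs)) - self.n_sex_ocrs
        if planted > max(0, int(n_free * (1 - self.frac_background))):
            raise ConfigurationError(
                "not enough non-promoter signal OCRs for the planted effects"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of every planted parameter; no hidden state."""

    true_specific_ocrs: dict[str, set[str]] = field(default_factory=dict)
    true_region_ocrs: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    true_norm_factors: pd.Series | None = None
    true_proportions: pd.DataFrame | None = None
    true_pi0: float | None = None
    planted_covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.true_proportions is not None:
            vals = self.true_proportions.values
            if (vals < 0).any():
                raise InputError("true proportions must be nonnegative")
            if np.abs(vals.sum(axis=1) - 1.0).max() > 1e-9:
                raise InputError("true proportions must sum to 1")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def _layout_ocrs(n_auto: int, n_sex: int, width: int = 500, gap: int = 500) -> OCRSet:
    ivs = [
        GenomicInterval("chr1", i * (width + gap), i * (width + gap) + width,
                        name=f"OCR_{i+1:05d}")
        for i in range(n_auto)
    ]
    ivs += [
        GenomicInterval("chrX", i * (width + gap), i * (width + gap) + width,
                        name=f"OCRX_{i+1:03d}")
        for i in range(n_sex)
    ]
    return OCRSet(ivs)


def simulate_sorted_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, OCRSet, GeneAnnotation, SyntheticTruth]:
    """Generate a full sorted-nuclei experiment with recorded ground truth.

    Expected counts factorize as baseline x cell effect x region effect x
    sex effect x FRiP allocation x library size. The FRiP allocation scales
    signal OCR means by frip_s / mean(frip) and background OCR means by
    (1 - frip_s) / (1 - mean(frip)), mimicking FRiP's signal-to-noise role.
    Promoter OCRs never carry planted differential effects, so they anchor
    the normalization; the implied true normalization factors are recorded.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_auto = config.n_ocrs - config.n_sex_ocrs
    ocrs = _layout_ocrs(n_auto, config.n_sex_ocrs)
    ids = ocrs.ids
    n = config.n_ocrs

    n_prom = int(round(config.frac_promoter * n))
    prom_idx = rng.choice(n_auto, size=n_prom, replace=False)
    promoter = np.zeros(n, dtype=bool)
    promoter[prom_idx] = True
    sex_idx = np.arange(n_auto, n)

    free = np.array(
        [i for i in range(n_auto) if not promoter[i]], dtype=int
    )
    rng.shuffle(free)
    n_bg = int(round(config.frac_background * free.size))
    background = np.zeros(n, dtype=bool)
    background[free[:n_bg]] = True

    baseline = np.empty(n)
    baseline[~promoter] = np.exp(rng.normal(0.0, 1.0, size=int((~promoter).sum())))
    baseline[promoter] = np.exp(rng.normal(2.0, 0.5, size=n_prom))
    baseline[background] = np.exp(rng.normal(-1.0, 0.5, size=n_bg))
    baseline = baseline / baseline.sum()

    # plant differential effects on robustly accessible OCRs: specific OCRs
    # are strong peaks, not the faint tail of the abundance distribution
    eligible = free[n_bg:]
    med = np.median(baseline[eligible])
    strong = eligible[baseline[eligible] >= med]
    weak = eligible[baseline[eligible] < med]
    rng.shuffle(strong)
    pool = list(strong) + list(weak)

    cell_ocrs: dict[str, np.ndarray] = {}
    for cell in config.cell_types:
        take, pool = pool[: config.n_specific_per_cell], pool[config.n_specific_per_cell:]
        cell_ocrs[cell] = np.array(take, dtype=int)
    region_ocrs: dict[tuple[str, str], np.ndarray] = {}
    for cell in config.cell_types:
        for region in config.regions:
            take, pool = pool[: config.n_region_specific], pool[config.n_region_specific:]
            region_ocrs[(cell, region)] = np.array(take, dtype=int)

    groups = [(c, r) for c in config.cell_types for r in config.regions]
    n_persons = config.n_samples_per_group
    persons = [f"P{i+1}" for i in range(n_persons)]
    sexes = {p: ("M" if i % 2 == 0 else "F") for i, p in enumerate(persons)}
    meta_rows, sample_ids = [], []
    for c, r in groups:
        for p in persons:
            sid = f"{c}_{r}_{p}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "cell_type": c, "region": r, "group": f"{c}_{r}",
                 "person": p, "sex": sexes[p]}
            )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    n_samp = len(metadata)
    frip = rng.uniform(*config.frip_range, size=n_samp)
    lib = rng.integers(config.library_size_range[0], config.library_size_range[1] + 1,
                       size=n_samp).astype(float)
    metadata["frip"] = frip
    for j in range(1, 4):  # pure-noise QC metrics
        metadata[f"qc_noise{j}"] = rng.normal(1.0, 0.1, size=n_samp)

    eff = np.tile(baseline[:, None], (1, n_samp))
    fc = 2.0 ** config.effect_log2fc
    for s_i, (_, row) in enumerate(metadata.iterrows()):
        cell, region, sex = row["cell_type"], row["region"], row["sex"]
        eff[cell_ocrs[cell], s_i] *= fc
        eff[region_ocrs[(cell, region)], s_i] *= fc
        if sex == "F":
            eff[sex_idx, s_i] *= 2.0 ** config.sex_log2fc
    mean_frip = frip.mean()
    alloc = np.where(
        background[:, None],
        (1.0 - frip[None, :]) / (1.0 - mean_frip),
        frip[None, :] / mean_frip,
    )
    mu = eff * alloc * lib[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)

    exp_colsum = mu.sum(axis=0)
    raw = (frip / mean_frip) * lib / exp_colsum
    true_factors = pd.Series(
        raw / np.exp(np.mean(np.log(raw))), index=sample_ids, name="true_norm_factor"
    )

    n_planted = (
        sum(len(v) for v in cell_ocrs.values())
        + sum(len(v) for v in region_ocrs.values())
        + len(sex_idx)
    )
    truth = SyntheticTruth(
        true_specific_ocrs={c: {ids[i] for i in v} for c, v in cell_ocrs.items()},
        true_region_ocrs={k: {ids[i] for i in v} for k, v in region_ocrs.items()},
        true_norm_factors=true_factors,
        true_pi0=1.0 - n_planted / n,
        planted_covariate_effects={
            "frip": {ids[i]: (-1.0 if background[i] else 1.0) for i in range(n)},
            "sex": {ids[i]: config.sex_log2fc for i in sex_idx},
        },
    )

    genes = pd.DataFrame(
        {
            "gene_id": [f"G{k+1:05d}" for k in range(n_prom)],
            "gene_name": [f"GENE{k+1}" for k in range(n_prom)],
            "biotype": "protein_coding",
            "chrom": "chr1",
            "strand": "+",
        }
    )
    tss = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "chrom": "chr1",
            "pos": [int(ocrs.intervals[i].midpoint) for i in sorted(prom_idx)],
        }
    )
    annotation = GeneAnnotation(genes=genes, tss=tss)
    cm = CountMatrix(counts, ids, sample_ids)
    return cm, metadata, ocrs, annotation, truth


def simulate_celltype_profiles(
    n_ocrs: int = 3000,
    cell_types: tuple[str, ...] = CELL_TYPES,
    between_cell_sd: float = 1.0,
    marker_log2fc: float = 3.0,
    n_markers_per_cell: int = 150,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-cell-type mean accessibility profiles with genome-wide differences.

    Cell types differ mildly at most OCRs (log2-normal factor with sd
    ``between_cell_sd``, emulating the broad between-cell-type divergence of
    chromatin) and strongly (``marker_log2fc``) at planted marker OCRs.
    Returns the OCR x cell-type profile matrix (arbitrary linear units) and
    the planted marker ids per cell type.
    """
    rng = np.random.default_rng(seed)
    ids = [f"OCR_{i+1:05d}" for i in range(n_ocrs)]
    baseline = np.exp(rng.normal(0.0, 1.0, size=n_ocrs))
    cellfac = 2.0 ** rng.normal(0.0, between_cell_sd, size=(n_ocrs, len(cell_types)))
    prof = baseline[:, None] * cellfac
    perm = rng.permutation(n_ocrs)
    markers: dict[str, list[str]] = {}
    for c_i, cell in enumerate(cell_types):
        take = perm[c_i * n_markers_per_cell: (c_i + 1) * n_markers_per_cell]
        markers[cell] = [ids[i] for i in sorted(take)]
        prof[take, c_i] *= 2.0 ** marker_log2fc
    return pd.DataFrame(prof, index=ids, columns=list(cell_types)), markers


def simulate_bulk_mixtures(
    reference_means: pd.DataFrame,
    n_samples: int,
    dirichlet_alpha: np.ndarray,
    case_effect: tuple[list[str], float] | None = None,
    depth: int = 1_000_000,
    seed: int = 0,
    nb_dispersion: float = 0.1,
    gc_log2fc: float = 0.0,
    proportions: np.ndarray | None = None,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Bulk samples as Dirichlet mixtures of per-cell-type OCR profiles.

    ``reference_means`` is OCR x cell type (nonnegative); each column is
    normalized to a probability profile and expected counts are
    depth x (profile @ theta), theta ~ Dirichlet(alpha). The second half of
    the samples are cases; ``case_effect`` = (ocr_ids, log2fc) multiplies
    case-sample means on those OCRs. A GC-content-like metadata covariate is
    drawn per sample and, when ``gc_log2fc`` is nonzero, scales a random
    half of the OCRs by 2**(gc_log2fc * standardized GC).
    """
    ref = reference_means.astype(float)
    if (ref.values < 0).any():
        raise InputError("reference profiles must be nonnegative")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape != (ref.shape[1],) or (alpha <= 0).any():
        raise InputError("dirichlet_alpha must be positive, one per cell type")
    rng = np.random.default_rng(seed)
    profiles = ref.values / ref.values.sum(axis=0, keepdims=True)
    if proportions is not None:
        theta = np.asarray(proportions, dtype=float)
        if theta.shape != (n_samples, ref.shape[1]):
            raise InputError("proportions must be n_samples x n_cell_types")
        if (theta < 0).any() or np.abs(theta.sum(axis=1) - 1.0).max() > 1e-9:
            raise InputError("supplied proportions must be a simplex per sample")
        rng.dirichlet(alpha, size=n_samples)  # keep the stream position stable
    else:
        theta = rng.dirichlet(alpha, size=n_samples)  # samples x cells
    mu = depth * (profiles @ theta.T)  # OCR x samples
    sample_ids = [f"BULK_{j+1:03d}" for j in range(n_samples)]
    diagnosis = np.array(
        ["control"] * (n_samples - n_samples // 2) + ["case"] * (n_samples // 2)
    )
    gc = rng.uniform(0.40, 0.50, size=n_samples)
    gc_ocrs: list[str] = []
    if gc_log2fc != 0.0:
        half = rng.choice(ref.shape[0], size=ref.shape[0] // 2, replace=False)
        gc_ocrs = [ref.index[i] for i in half]
        z = (gc - gc.mean()) / max(gc.std(), 1e-12)
        mu[half, :] *= 2.0 ** (gc_log2fc * z[None, :])
    if case_effect is not None:
        ocr_ids, log2fc = case_effect
        missing = set(ocr_ids) - set(ref.index)
        if missing:
            raise InputError(f"case-effect OCRs not in profile: {sorted(missing)[:5]}")
        rows = [ref.index.get_loc(o) for o in ocr_ids]
        is_case = diagnosis == "case"
        mu[np.ix_(rows, np.flatnonzero(is_case))] *= 2.0 ** log2fc
    counts = _nb_draw(rng, mu, nb_dispersion)
    metadata = pd.DataFrame(
        {"diagnosis": diagnosis, "gc_content": gc,
         "sex": ["M" if j % 2 == 0 else "F" for j in range(n_samples)]},
        index=sample_ids,
    )
    truth = SyntheticTruth(
        true_proportions=pd.DataFrame(theta, index=sample_ids, columns=ref.columns),
        planted_covariate_effects={
            "diagnosis": (
                {o: case_effect[1] for o in case_effect[0]} if case_effect else {}
            ),
            "gc_content": {o: gc_log2fc for o in gc_ocrs},
        },
    )
    cm = CountMatrix(counts, list(ref.index), sample_ids)
    return cm, metadata, truth


def simulate_footprints(
    ocrs: OCRSet,
    motif_counts: dict[str, int],
    redundant_pairs: list[tuple[str, str]] = (),
    seed: int = 0,
    site_width: int = 10,
    group: str = "",
) -> list[BindingSite]:
    """Footprinted binding sites placed inside OCRs, probabilities in [0,1].

    For each declared redundant pair (a, b), at least 50% of b's sites are
    copied from a's positions so the pair trips the positional-redundancy
    rule downstream.
    """
    for m, c in motif_counts.items():
        if c < 0:
            raise InputError(f"negative site count for motif {m}")
    if len(ocrs) == 0 and any(c > 0 for c in motif_counts.values()):
        raise InputError("cannot place sites: OCR set is empty")
    rng = np.random.default_rng(seed)
    placed: dict[str, list[BindingSite]] = {}

    def place(motif: str, count: int) -> list[BindingSite]:
        out = []
        for _ in range(count):
            iv = ocrs.intervals[int(rng.integers(0, len(ocrs)))]
            w = min(site_width, len(iv))
            s = int(rng.integers(iv.start, iv.end - w + 1))
            out.append(
                BindingSite(motif, GenomicInterval(iv.chrom, s, s + w),
                            p_bind=float(rng.uniform(0.5, 1.0)), group=group)
            )
        return out

    copied_into = {b: a for a, b in redundant_pairs}
    for motif in sorted(motif_counts):
        if motif in copied_into and copied_into[motif] in placed:
            src = placed[copied_into[motif]]
            count = motif_counts[motif]
            # share >=50% of the smaller motif's positions with the source
            n_copy = min(len(src), count, max(int(np.ceil(0.5 * count)), 1))
            if len(src) <= count:
                n_copy = min(len(src), count)
            chosen = rng.choice(len(src), size=n_copy, replace=False)
            sites = [
                BindingSite(motif, src[i].interval, float(rng.uniform(0.5, 1.0)), group)
                for i in chosen
            ]
            sites += place(motif, count - len(sites))
            placed[motif] = sites
        else:
            placed[motif] = place(motif, motif_counts[motif])
    return [s for m in sorted(placed) for s in placed[m]]


def simulate_pvalues(
    n: int, pi0: float, alt_shape: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Mixture of null Uniform(0,1) and alternative Beta(alt_shape, 1)
    p-values: round(pi0 * n) null draws, the rest alternative."""
    if n <= 0:
        raise ConfigurationError("n must be positive")
    if not (0.0 <= pi0 <= 1.0):
        raise ConfigurationError("pi0 must be in [0,1]")
    if alt_shape >= 1.0 or alt_shape <= 0.0:
        raise ConfigurationError("alt_shape must lie in (0,1)")
    rng = np.random.default_rng(seed)
    n_null = int(round(pi0 * n))
    p = np.concatenate([
        rng.uniform(0.0, 1.0, size=n_null),
        rng.beta(alt_shape, 1.0, size=n - n_null),
    ])
    rng.shuffle(p)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def save_simulation(
    outdir,
    counts: CountMatrix,
    metadata: pd.DataFrame,
    ocrs: OCRSet,
    annotation: GeneAnnotation,
    truth: SyntheticTruth,
) -> None:
    """Write counts TSV, metadata TSV, OCR BED4, gene TSV and truth JSON."""
    from .io import write_bed, write_counts_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_tsv(counts.to_frame(), outdir / "counts.tsv")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    write_bed(ocrs.intervals, outdir / "ocrs.bed")
    annotation.genes.merge(annotation.tss, on="gene_id").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    payload = {
        "true_specific_ocrs": {k: sorted(v) for k, v in truth.true_specific_ocrs.items()},
        "true_region_ocrs": {
            f"{c}|{r}": sorted(v) for (c, r), v in truth.true_region_ocrs.items()
        },
        "true_norm_factors": (
            truth.true_norm_factors.to_dict() if truth.true_norm_factors is not None else None
        ),
        "true_pi0": truth.true_pi0,
        "planted_covariate_effects": truth.planted_covariate_effects,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
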