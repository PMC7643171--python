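# Methods

This note documents the statistical models implemented in `ocrcell`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and known limitations.

## Data model

The unit of analysis is the open chromatin region (OCR): a 0-based
half-open genomic interval from a consensus peak set. Consensus
construction takes the union of per-group peak calls, merges overlapping
(and bookended) peaks into maximal non-overlapping intervals, and removes
entirely any merged interval sharing ≥1 bp with a blacklisted region —
removal, not trimming, because a blacklist overlap discredits the whole
peak call. Accessibility is measured as the number of fragments
overlapping an OCR by ≥1 bp (featureCounts/bedtools semantics); since
consensus OCRs are disjoint, a fragment adds at most one count per OCR.

QC metrics: FRiP is the fraction of fragments overlapping any OCR; PBC is
distinct (chromosome, start, strand) positions over total reads; TSS
enrichment aggregates per-bp fragment coverage over ±1 kb windows around
TSSs and divides the coverage at the TSS by the mean coverage of the
outermost 100 bp on each side. When the flank baseline is zero but the
window is covered, the baseline falls back to the window-wide mean (the
score must be 1 under uniform coverage and 0 with no coverage; the
fallback keeps the score finite in between). External TSS-enrichment
tools aggregate somewhat differently; this contract is a deliberate,
simple stand-in.

## Promoter-anchored TMM

Between-sample scaling uses trimmed mean of M-values restricted to OCRs
that directly overlap an autosomal protein-coding TSS. Rationale: cell
types differ in the promoter/non-promoter composition of their open
chromatin, and the log transform inside TMM overweights the weaker
non-promoter OCRs, skewing standard TMM; promoter OCRs behave like a
housekeeping anchor.

Internals follow the published TMM definition (configurable): 30%
two-sided trim on M, 5% on A, delta-method precision weights, features
with zero counts in either sample excluded. Library sizes are the full
column sums (the factor multiplies the library size, edgeR convention).
To avoid an arbitrary reference, the factor for each sample is the
arithmetic mean of its pairwise factor over *every* choice of reference
sample, the self-reference contributing exactly 1, followed by rescaling
to geometric mean 1. Including the self-reference is not cosmetic: with it
the promoter-anchored effective library size `N_s·f_s` is algebraically
exact — under planted per-sample scalings it equals the true anchor up to
one global constant, and adding cell-specific non-promoter OCRs leaves it
unchanged. Excluding the self-reference leaves each sample's average
missing its own library size and breaks both properties at the
few-percent level. The per-reference factor matrix is available for
reference-choice robustness reporting (on balanced data the per-reference
standard deviation is of order 0.01).

The linear-vs-log question for "the mean of the factors" is resolved as
the arithmetic mean of linear-scale factors; geometric-mean rescaling
makes the alternative differ only by a global constant.

log-CPM: `log2((y + 0.5) / (lib·f + 1) · 1e6)`; prior count 0.5 is the
conventional default.

## Covariate model

The accessibility model is, per OCR,
`accessibility ~ cell_type:region + sex + FRiP` under cell-means coding of
the 12 cell-by-region groups — 12 + 1 + 1 = 14 estimated mean parameters.

*Metric centering.* QC metrics with cell-type-dependent distributions are
divided by their per-cell-type median (all such metrics are positive
ratios); an additive mode exists for metrics that can be nonpositive.

*PCA screen.* PCA is run within each cell type (otherwise the leading
components encode cell identity); components explaining >1% of variance
are Pearson-correlated with each candidate; Benjamini–Hochberg across all
(candidate, PC, cell type) tests at a lenient FDR of 0.2 admits candidates
to the BIC stage.

*Net-BIC forward selection.* For each candidate, per-OCR models are fitted
with and without it; ΔBIC ≤ −2 counts as improved, ΔBIC ≥ +2 as worsened
(2 being the lower bound of positive evidence; the boundary is inclusive),
and the candidate with the largest net share (improved − worsened)/G is
added if the share is ≥5%, iterating against the grown model. Squared
terms of selected numeric covariates are tested afterwards the same way.
BIC uses the Gaussian log-likelihood with k coefficients + 1 variance
parameter. Ties break lexicographically, making the procedure invariant
to candidate ordering.

*Variance fractions.* Per-OCR sequential (type-I) ANOVA in the given term
order: each term's sum of squares is the drop in residual SS when added,
divided by the centered total SS. Sequential decomposition is used instead
of type-II because fractions plus residual must sum to exactly 1 for every
OCR on any design, which type-II guarantees only for orthogonal designs;
on balanced designs such as the sorted study the two coincide.

## Differential accessibility

*Precision weights.* Following the voom recipe: per-OCR OLS on log-CPM, a
lowess smooth (span 0.5) of the square-root residual standard deviation
against average log-count, and observation weights equal to the predicted
sqrt-sd at each observation's fitted log-count raised to the power −4.
Sample-level weights use one round of per-sample variance estimation on
the obs-weighted residuals, normalized to geometric mean 1; the combined
weight is the product. The one-round simplification (in place of an
iterative REML scheme) preserves the contract behavior — noisy samples
are down-weighted — and is the component the tests pin down.

*Moderated tests.* Weighted least squares per OCR; residual variances are
shrunk toward a scaled inverse-chi-square prior whose parameters (d₀, s₀²)
are moment-matched on log variances (trigamma inversion by Newton
iteration); moderated t has n − k + d₀ degrees of freedom. The
implementation reproduces the reference R implementation to machine
precision on shared inputs (tested). Plain WLS t-tests are available via
`moderate=False`.

*Contrasts.* Pairwise cell contrasts are region-summed: the GLU-vs-GABA
contrast averages (GLU_r − GABA_r) over the three regions, so regional
composition cancels. Regional contrasts test one region against the mean
of the others within a cell type, with BH adjustment restricted to the
OCRs called in that cell type (power increase by restriction).

*Specificity sets.* Cell-specific = significantly more accessible (FDR 5%,
positive fold change) than *each* other cell type; the reported statistics
are those of the least significant comparison (ties by smaller |log₂FC|).
Neuron = (GLU>OLIG ∩ GLU>MGAS) ∪ (GABA>OLIG ∩ GABA>MGAS); nonNeuron is the
mirror image. For group sets the reported statistics come from the
satisfied branch whose least significant comparison is most significant.
The four cell sets are disjoint by construction, and each is contained in
its group set; the test suite verifies the algebra against brute-force
evaluation of the definitions over all 3⁶ significance patterns of the six
pairwise comparisons.

*Residualization.* The nuisance effect (sex, FRiP) is removed by
subtracting `X_remove · β̂_remove` from the full-model fit, retaining the
cell/region structure; the operation is idempotent and leaves a zero
post-hoc nuisance coefficient.

## pi1

π₀ is estimated by the smoother method: π₀(λ) = #{p > λ}/((1−λ)n) on the
λ grid 0.05–0.95 (step 0.05), a cubic polynomial fitted with precision
weights proportional to (1 − λ) — the variance of π₀(λ) grows like
1/(1 − λ) — evaluated at the largest λ and clamped to [0, 1]; π₁ = 1 − π₀.
A fixed-λ estimator (`method="fixed"`) is available. Calibration
properties of the smoother hold in seed-averaged form: the raw estimator
at λ = 0.95 alone carries a binomial standard deviation of ≈0.044 at
n = 10,000, so individual-seed estimates of π₁ scatter by several
hundredths around truth for any variant of this estimator family; the
seed-averaged error across a π₀ grid is ≤0.025 (measured).

The pairwise π₁ matrix fits the full 12-group model once and evaluates
all 66 pairwise group contrasts; aggregations (e.g. median π₁ over all
neuronal-vs-non-neuronal group pairs) summarize group dissimilarity.

## Overlap and enrichment

Genomic context uses the priority promoter (±3 kb of any TSS) > 5′-UTR >
3′-UTR > exon > intron > distal intergenic; with a TSS-only annotation
only promoter/distal are assigned. Jaccard is base-pair intersection over
union of the merged interval sets. Regulatory domains follow basal-plus-
extension defaults (5 kb upstream, 1 kb downstream, extension to 1 Mb
capped at the neighboring basal domain); gene-set enrichment compares OCR
density in the gene set's domain union against all domains with a
one-sided binomial tail on the bp coverage fraction. TSS direct mapping
back-transforms residualized log-CPM (2^x) to a linear scale before
summing per gene over TSS-overlapping OCRs — fractions of linear-scale
accessibility are interpretable as read fractions; genes without a
TSS-overlapping OCR are excluded. Credible-variant enrichment is a 2×2
Fisher exact test (Haldane 0.5 correction, flagged, for degenerate
tables), with an optional permutation null that repositions each OCR
uniformly on its own chromosome preserving length;
p_emp = (1 + #{OR_perm ≥ OR_obs})/(1 + n_perm).

## TF-footprint burden

Overlapping same-motif sites (palindromic calls and the like) are
deduplicated greedily by descending binding probability (ties: leftmost).
Motif redundancy: a pair is redundant when ≥50% of the smaller motif's
sites each overlap a site of the other motif by ≥50% of the shorter
site's length; the most redundant pair is resolved by dropping the motif
with fewer sites (ties: lexicographically larger id), iterating to a
fixed point. A site's weight on a gene is
p_bind · exp(−d / decay_scale) with d the midpoint-to-nearest-TSS
distance, clipped to 0 beyond 10 decay scales; the decay scale defaults to
10 kb (configurable — a constant of this order makes promoter-proximal
sites dominate while retaining distal enhancer contributions). Burden is
the sum over non-redundant-motif sites. Group comparisons rank genes by
the burden difference of each cross-group sample pair with centered ranks
−(n−1)/2 … (n−1)/2 (average ranks on ties, each pair summing to 0) and
average over pairs. Motif enrichment in cell-specific OCRs counts bound
sites (p_bind ≥ 0.9, configurable) in target vs background OCR sets and
tests k of n successes against π = bp(target)/(bp(target)+bp(background))
with a one-sided binomial tail, Bonferroni over the motifs tested.

## Deconvolution and the case-control workflow

Markers are cell-specific OCRs at FDR < 5% and log₂FC > 2 against every
other cell type. Proportions solve min‖y − Rθ‖² subject to θ ≥ 0,
Σθ = 1, where y is the bulk sample's linear-scale CPM on marker OCRs and
R the reference profile matrix; the simplex constraint is imposed through
nonnegative least squares on a system augmented with a strongly weighted
sum-to-one row, followed by exact renormalization (solver deviation
< 1e−6). Estimates are scale-invariant in the bulk counts because y is
CPM.

The case-control workflow TMM-normalizes the bulk counts by default
before modeling: a concentrated differential signal otherwise shifts the
library sizes of one diagnosis group and imprints a spurious
opposite-direction effect on every other OCR through the CPM denominator
(measured: null p < 0.05 at ~9% instead of 5% without normalization).
Composition covariates (estimated proportions, one column dropped to
avoid simplex collinearity with the intercept) and any supplied numeric
covariates (e.g. a GC-content metric) enter through the same net-BIC
forward selection as the cohort model; the diagnosis contrast is then
fitted without and with the selected composition columns and π₁ computed
from each, plus π₁ restricted to each cell type's specific OCRs.

## Synthetic data: what it emulates, and what it does not

`simulate_sorted_experiment` draws negative-binomial counts with expected
value baseline × cell effect × region effect × sex effect × FRiP
allocation × library size. The FRiP covariate acts as signal allocation:
signal-OCR means scale with frip/mean(frip), background-OCR means with
(1−frip)/(1−mean(frip)) — FRiP behaves as a signal-to-noise parameter.
Promoter OCRs (30% of OCRs, matching sorted brain chromatin) never carry
planted differential effects, so they anchor normalization; the implied
true normalization factors are recorded. Sex effects (log₂FC 2, ~5 OCRs)
sit on sex-chromosome OCRs. Cell/region-specific effects are planted on
OCRs of at least median baseline accessibility — cell-specific OCRs in
real data are robust peaks, not the faintest tail. Dispersion defaults to
0.01 (biological CV 0.1), representing uniformly processed sorted-nuclei
replicates from the same few donors; with per-sample depth of 10⁶
fragments this makes the total per-observation variance budget
(φ + 1/μ ≈ 0.02 at the typical planted-OCR abundance) consistent with the
pipeline's design goal of estimating a log₂FC of 2 within ±0.2.

`simulate_celltype_profiles` produces reference accessibility profiles
with genome-wide mild divergence between cell types (log₂-normal factor,
sd 1) plus strong planted markers — mirroring the observation that most
OCRs differ somewhat between cell types (between-cell π₁ of order 0.7 in
sorted data). `simulate_bulk_mixtures` mixes these profiles with
Dirichlet-drawn (or user-supplied) proportions at a target depth,
bulk-typical dispersion, an optional planted case effect, and a GC-like
metadata covariate. The case-control power scenario uses a composition-
matched design — cases and controls share the same drawn proportion
vectors — realizing exactly the condition "composition varies
independently of diagnosis": with independent draws at cohort sizes of a
few dozen, chance diagnosis–composition correlation creates genuine
confounded signal that adjustment removes, which is a different phenomenon
from the power gain under study.

Not emulated: raw reads, alignment or peak calling; linkage
disequilibrium or GWAS summary structure; batch/person random effects;
GC-dependent amplification beyond the optional planted covariate; spatial
correlation along the genome (OCR counts are independent given their
means). Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed count model, not robustness to
artifacts absent from that model.

## Scenario sizes

The study scenarios (tests and `scripts/acceptance.py`) run at desk scale,
chosen to exercise the full design while completing in about a minute:
2,000–5,000 OCRs, the full 12-group design with 1 or 4 samples per group,
per-sample depth 10⁶, bulk cohorts of 40–50 samples, 20–100 seeded
replicates per calibration. These sizes reproduce the qualitative and
calibration behavior of the genome-scale setting; absolute discovery
counts naturally scale with OCR number and cohort size.

## Known limitations

- The sample-weight estimate is a single-pass approximation; extremely
  discrepant sample variances would be better served by an iterative fit.
- The π₀ smoother inherits the boundary variance of all λ-extrapolation
  estimators; single-dataset π₁ values carry an uncertainty of a few
  hundredths at n = 10⁴ tests.
- `variance_fractions` is order-dependent on unbalanced designs (sequential
  decomposition); report the order with the result.
- The permutation null for variant enrichment repositions OCRs uniformly
  per chromosome, ignoring accessibility-correlated genomic covariates
  (GC, gene density); enrichment against structured backgrounds should be
  interpreted accordingly.
- The regulatory-burden decay constant (10 kb) is a field-typical default,
  not a fitted quantity.
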