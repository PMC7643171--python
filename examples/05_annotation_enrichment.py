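"""Genomic-context annotation, Jaccard overlap, gene-set enrichment and
credible-variant enrichment.

Annotates OCRs by genomic context (promoter > UTRs > exon > intron >
distal), measures base-pair Jaccard overlap between interval sets,
computes a regulatory-domain binomial gene-set enrichment, and tests
whether fine-mapped (credible-set) variants concentrate inside OCRs with a
Fisher exact test plus a positional permutation null.
"""

import numpy as np
import pandas as pd

from ocrcell.intervals import GenomicInterval, OCRSet
from ocrcell.overlap import (
    GeneAnnotation,
    annotate_context,
    eqtl_enrichment,
    great_enrichment,
    jaccard_bp,
    regulatory_domains,
)

genes = pd.DataFrame(
    {"gene_id": [f"g{i}" for i in range(6)],
     "gene_name": [f"GENE{i}" for i in range(6)],
     "biotype": "protein_coding", "chrom": "chr1", "strand": "+"}
)
tss = pd.DataFrame({"gene_id": genes["gene_id"], "chrom": "chr1",
                    "pos": [(i + 1) * 50_000 for i in range(6)]})
annotation = GeneAnnotation(genes=genes, tss=tss)

ocrs = OCRSet([
    GenomicInterval("chr1", 49_000, 49_400),    # near g0's TSS
    GenomicInterval("chr1", 75_000, 75_400),    # between genes
    GenomicInterval("chr1", 148_500, 148_900),  # near g2's TSS
    GenomicInterval("chr1", 500_000, 500_400),
])
ctx = annotate_context(ocrs, annotation, promoter_window=3000)
print("genomic context (promoter = within 3 kb of a TSS):")
print(ctx.value_counts().to_string())

a = [GenomicInterval("chr1", 0, 1000)]
b = [GenomicInterval("chr1", 500, 1500)]
print(f"\nJaccard(bp) of [0,1000) vs [500,1500): {jaccard_bp(a, b):.4f} "
      "(500 shared / 1500 union bp)")

domains = regulatory_domains(annotation)
fold, p = great_enrichment(ocrs, domains, {"g0", "g2"})
print(f"gene-set enrichment for {{g0, g2}}: fold = {fold:.2f}, "
      f"one-sided binomial p = {p:.4f}")

rng = np.random.default_rng(0)
in_pos = [int(rng.integers(iv.start, iv.end)) for iv in ocrs for _ in range(6)]
out_pos = list(rng.integers(0, 600_000, 400))
variants = pd.DataFrame({
    "chrom": "chr1",
    "pos": in_pos + out_pos,
    "credible": [1] * len(in_pos) + list(rng.integers(0, 2, len(out_pos))),
})
res = eqtl_enrichment(ocrs, variants, padding=0, n_perm=199, seed=1)
print(f"credible-variant enrichment in OCRs: OR = {res['odds_ratio']:.2f}, "
      f"Fisher p = {res['fisher_p']:.2e}, permutation p = {res['empirical_p']:.4f}")
print("(credible variants planted inside OCRs are detected against the "
      "genome-wide background)")
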