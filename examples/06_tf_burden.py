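"""TF-footprint regulatory burden and motif enrichment.

Footprinted binding sites (with binding probabilities) are deduplicated per
motif, motifs with redundant site sets are pruned, gene-level regulatory
burden is computed as a TSS-distance-decaying sum of binding probabilities,
group differences are aggregated with centered ranks, and motif
overrepresentation in cell-specific OCRs is tested with a coverage-aware
binomial test.
"""

import numpy as np

from ocrcell import simulate
from ocrcell.footprints import (
    burden_matrix,
    dedupe_sites,
    motif_enrichment,
    prune_motifs,
    rank_aggregate,
)
from ocrcell.intervals import GenomicInterval, OCRSet

ocrs = OCRSet([GenomicInterval("chr1", i * 5000, i * 5000 + 800) for i in range(40)])
sites = simulate.simulate_footprints(
    ocrs, {"SOX10": 60, "SOX10_alt": 60, "NEUROD2": 50},
    redundant_pairs=[("SOX10", "SOX10_alt")], seed=3,
)
by_motif = {}
for s in sites:
    by_motif.setdefault(s.motif_id, []).append(s)

deduped = {m: dedupe_sites(v) for m, v in by_motif.items()}
print({m: f"{len(by_motif[m])} -> {len(deduped[m])} sites after dedup"
       for m in sorted(by_motif)})
surviving = prune_motifs(deduped)
print(f"non-redundant motifs (50%/50% rule): {sorted(surviving)} "
      "(the redundant SOX10 copy is removed)")

# burden on two genes, with sites assigned to groups for the comparison
gene_tss = {"GENE_A": [2_500], "GENE_B": [150_000]}
flat = [s for m in surviving for s in deduped[m]]
groups = ["GLU", "MGAS"]
regrouped = [type(s)(s.motif_id, s.interval, s.p_bind, groups[i % 2])
             for i, s in enumerate(flat)]
burden = burden_matrix(regrouped, gene_tss, decay_scale=10_000, motif_set=surviving)
print("gene x group regulatory burden (decay scale 10 kb):")
print(burden.scores.round(3).to_string())
score = rank_aggregate(burden, ["GLU"], ["MGAS"])
print(f"centered-rank score GLU vs MGAS: {score.round(2).to_dict()} "
      "(positive = more GLU-regulated; ranks sum to 0)")

target = OCRSet([GenomicInterval("chr1", i * 5000, i * 5000 + 800)
                 for i in range(0, 20)])
background = OCRSet([GenomicInterval("chr1", i * 5000, i * 5000 + 800)
                     for i in range(20, 40)])
enr = motif_enrichment(sites, target, background, p_bind_threshold=0.9)
print("coverage-aware binomial motif enrichment (target = first 20 OCRs):")
print(enr.loc[~enr["skipped"], ["n", "k", "fold", "p", "p_bonferroni"]]
      .round(4).to_string())
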