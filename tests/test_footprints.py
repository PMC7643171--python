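"""Footprint dedup, motif pruning, decay burden, rank aggregation and
coverage-aware motif enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ocrcell.exceptions import InputError
from ocrcell.footprints import (
    BindingSite,
    RegulatoryBurden,
    burden_matrix,
    dedupe_sites,
    motif_enrichment,
    prune_motifs,
    rank_aggregate,
    site_gene_weight,
)
from ocrcell.intervals import GenomicInterval, OCRSet


def site(motif, start, end, p, chrom="chr1", group=""):
    return BindingSite(motif, GenomicInterval(chrom, start, end), p, group)


def brute_force_dedupe(sites):
    """Greedy-by-probability oracle over the overlap graph."""
    remaining = sorted(
        sites, key=lambda s: (-s.p_bind, s.interval.chrom, s.interval.start, s.interval.end)
    )
    kept = []
    for s in remaining:
        if not any(
            k.motif_id == s.motif_id and k.group == s.group
            and k.interval.chrom == s.interval.chrom
            and k.interval.start < s.interval.end and s.interval.start < k.interval.end
            for k in kept
        ):
            kept.append(s)
    return sorted(kept, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))


class TestDedupeSites:
    def test_keeps_highest_probability(self):
        a, b = site("m", 0, 10, 0.9), site("m", 5, 15, 0.8)
        assert dedupe_sites([a, b]) == [a]

    def test_non_overlapping_untouched(self):
        a, b = site("m", 0, 10, 0.5), site("m", 20, 30, 0.9)
        assert dedupe_sites([a, b]) == [a, b]

    def test_chain_matches_greedy_oracle(self):
        # chain of three mutually overlapping pairs: middle has the best p
        chain = [site("m", 0, 10, 0.7), site("m", 5, 15, 0.95), site("m", 12, 22, 0.8)]
        out = dedupe_sites(chain)
        assert out == brute_force_dedupe(chain)
        assert [s.interval.start for s in out] == [5]

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sites = [
                site("m", int(s), int(s) + int(w), float(np.round(p, 3)))
                for s, w, p in zip(
                    rng.integers(0, 100, 12), rng.integers(3, 15, 12),
                    rng.uniform(0, 1, 12)
                )
            ]
            assert dedupe_sites(sites) == brute_force_dedupe(sites)

    def test_tie_breaks_leftmost(self):
        a, b = site("m", 5, 15, 0.8), site("m", 0, 10, 0.8)
        assert dedupe_sites([a, b]) == [b]


def brute_force_prune(sites_by_motif, share=0.5, pos=0.5):
    alive = {m: list(v) for m, v in sites_by_motif.items()}

    def match_share(a, b):
        if not a:
            return 0.0
        hit = 0
        for sa in a:
            for sb in b:
                ov = min(sa.interval.end, sb.interval.end) - max(
                    sa.interval.start, sb.interval.start
                )
                if sa.interval.chrom == sb.interval.chrom and ov >= pos * min(
                    len(sa.interval), len(sb.interval)
                ):
                    hit += 1
                    break
        return hit / len(a)

    while True:
        best, pair = 0.0, None
        ms = sorted(alive)
        for i, m1 in enumerate(ms):
            for m2 in ms[i + 1:]:
                small, big = (
                    (alive[m1], alive[m2])
                    if len(alive[m1]) <= len(alive[m2])
                    else (alive[m2], alive[m1])
                )
                r = match_share(small, big)
                if r >= share and r > best:
                    best, pair = r, (m1, m2)
        if pair is None:
            return set(alive)
        m1, m2 = pair
        if len(alive[m1]) != len(alive[m2]):
            drop = m1 if len(alive[m1]) < len(alive[m2]) else m2
        else:
            drop = max(m1, m2)
        del alive[drop]


class TestPruneMotifs:
    def test_identical_site_sets_reduced_to_one(self):
        s = [site("a", 0, 10, 0.9), site("a", 50, 60, 0.9)]
        t = [site("b", 0, 10, 0.8), site("b", 50, 60, 0.8)]
        out = prune_motifs({"a": s, "b": t})
        assert len(out) == 1

    def test_disjoint_motifs_both_kept(self):
        out = prune_motifs({
            "a": [site("a", 0, 10, 0.9)],
            "b": [site("b", 100, 110, 0.9)],
        })
        assert out == {"a", "b"}

    def test_chain_matches_iterative_oracle(self):
        # A overlaps B, B overlaps C, A and C disjoint
        sites = {
            "A": [site("A", 0, 10, 0.9), site("A", 100, 110, 0.9)],
            "B": [site("B", 0, 10, 0.9), site("B", 200, 210, 0.9),
                  site("B", 300, 310, 0.9)],
            "C": [site("C", 200, 210, 0.9), site("C", 300, 310, 0.9)],
        }
        assert prune_motifs(sites) == brute_force_prune(sites)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            sites = {}
            for m in "abcd":
                n = int(rng.integers(1, 6))
                sites[m] = [
                    site(m, int(s) * 10, int(s) * 10 + 8, 0.9)
                    for s in rng.integers(0, 10, n)
                ]
            assert prune_motifs(sites) == brute_force_prune(sites)

    def test_keep_rule_prefers_more_sites(self):
        big = [site("big", i * 20, i * 20 + 10, 0.9) for i in range(4)]
        small = [site("small", 0, 10, 0.9), site("small", 20, 30, 0.9)]
        assert prune_motifs({"big": big, "small": small}) == {"big"}

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            prune_motifs({})


class TestSiteGeneWeight:
    def test_zero_distance_gives_p_bind(self):
        s = site("m", 95, 105, 0.7)
        assert site_gene_weight(s, [100], 10_000) == pytest.approx(0.7)

    def test_one_decay_scale(self):
        s = site("m", 9_995, 10_005, 1.0)
        w = site_gene_weight(s, [0], 10_000)
        assert w == pytest.approx(np.exp(-1), abs=1e-9)
        assert w == pytest.approx(0.3679, abs=1e-4)

    def test_strictly_decreasing_in_distance(self):
        ws = [
            site_gene_weight(site("m", d, d + 10, 1.0), [0], 1000)
            for d in range(0, 9000, 500)
        ]
        assert all(a > b for a, b in zip(ws, ws[1:]))

    def test_hard_cutoff_at_ten_scales(self):
        s = site("m", 100_000, 100_010, 1.0)
        assert site_gene_weight(s, [0], 1000) == 0.0


class TestBurdenMatrix:
    def test_single_site_burden_equals_weight(self):
        s = site("m", 1000, 1010, 0.8, group="GLU")
        burden = burden_matrix([s], {"g": [1005]}, decay_scale=1000, motif_set={"m"})
        assert burden.scores.loc["g", "GLU"] == pytest.approx(0.8)

    def test_gene_beyond_cutoff_zero(self):
        s = site("m", 0, 10, 0.8, group="GLU")
        burden = burden_matrix([s], {"g": [100_000]}, decay_scale=1000, motif_set={"m"})
        assert burden.scores.loc["g", "GLU"] == 0.0

    def test_redundant_motif_duplication_invariant(self):
        sites = [site("a", 100, 110, 0.9, group="x"),
                 site("a", 300, 310, 0.7, group="x")]
        dup = [site("b", s.interval.start, s.interval.end, s.p_bind, group="x")
               for s in sites]
        b1 = burden_matrix(sites, {"g": [105]}, decay_scale=1000)
        b2 = burden_matrix(sites + dup, {"g": [105]}, decay_scale=1000)
        assert np.allclose(b1.scores.values, b2.scores.values)


class TestRankAggregate:
    def _burden(self, values):
        scores = pd.DataFrame(values, columns=["s1", "s2"])
        scores.index = [f"g{i}" for i in range(len(scores))]
        return RegulatoryBurden(scores, decay_scale=1000, motif_set=frozenset("m"))

    def test_three_genes_centered_ranks(self):
        burden = self._burden([[3.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        score = rank_aggregate(burden, ["s1"], ["s2"])
        assert sorted(score.tolist()) == [-1.0, 0.0, 1.0]
        assert score["g0"] == 1.0  # largest difference

    def test_ranks_sum_to_zero(self):
        rng = np.random.default_rng(2)
        burden = self._burden(rng.uniform(0, 5, size=(11, 2)))
        score = rank_aggregate(burden, ["s1"], ["s2"])
        assert score.sum() == pytest.approx(0.0, abs=1e-9)
        n = len(score)
        assert score.max() <= (n - 1) / 2 and score.min() >= -(n - 1) / 2

    def test_swapping_sides_negates(self):
        rng = np.random.default_rng(3)
        burden = self._burden(rng.uniform(0, 5, size=(7, 2)))
        a = rank_aggregate(burden, ["s1"], ["s2"])
        b = rank_aggregate(burden, ["s2"], ["s1"])
        assert np.allclose(a.values, -b.values)

    def test_empty_side_rejected(self):
        burden = self._burden([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(InputError):
            rank_aggregate(burden, [], ["s2"])


class TestMotifEnrichment:
    def _ocrs(self):
        target = OCRSet([GenomicInterval("chr1", 0, 1000)])
        background = OCRSet([GenomicInterval("chr1", 10_000, 11_000)])
        return target, background

    def test_all_sites_in_target_closed_form(self):
        target, background = self._ocrs()
        sites = [site("m", 10 * i, 10 * i + 8, 0.95) for i in range(20)]
        out = motif_enrichment(sites, target, background)
        # pi = 0.5, all 20 in target: p = 0.5^20
        assert out.loc["m", "fold"] == pytest.approx(2.0)
        assert out.loc["m", "p"] == pytest.approx(0.5 ** 20, rel=1e-9)
        assert out.loc["m", "p"] == pytest.approx(9.5367e-7, rel=1e-4)

    def test_exact_binomial_tail_agreement(self):
        target, background = self._ocrs()
        sites = [site("m", 10 * i, 10 * i + 8, 0.95) for i in range(7)] + [
            site("m", 10_000 + 10 * i, 10_008 + 10 * i, 0.95) for i in range(5)
        ]
        out = motif_enrichment(sites, target, background)
        exact = sum(stats.binom.pmf(k, 12, 0.5) for k in range(7, 13))
        assert out.loc["m", "p"] == pytest.approx(exact, abs=1e-12)

    def test_below_threshold_sites_ignored(self):
        target, background = self._ocrs()
        sites = [site("m", 0, 8, 0.5)]
        out = motif_enrichment(sites, target, background)
        assert out.loc["m", "skipped"]

    def test_bonferroni_counts_tested_motifs(self):
        target, background = self._ocrs()
        sites = [site("a", 0, 8, 0.95), site("b", 10, 18, 0.95),
                 site("c", 50_000, 50_008, 0.95)]  # c outside both -> skipped
        out = motif_enrichment(sites, target, background)
        assert out.loc["a", "p_bonferroni"] == pytest.approx(
            min(1.0, out.loc["a", "p"] * 2)
        )

    def test_uniform_coverage_placement_is_null(self):
        rng = np.random.default_rng(4)
        target = OCRSet([GenomicInterval("chr1", i * 2000, i * 2000 + 1000)
                         for i in range(5)])
        background = OCRSet([GenomicInterval("chr2", i * 2000, i * 2000 + 1000)
                             for i in range(5)])
        sig = 0
        n_seeds = 30
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            sites = []
            for i in range(40):
                if r.uniform() < 0.5:
                    base, chrom = int(r.integers(0, 5)) * 2000, "chr1"
                else:
                    base, chrom = int(r.integers(0, 5)) * 2000, "chr2"
                s = base + int(r.integers(0, 990))
                sites.append(site("m", s, s + 8, 0.95, chrom=chrom))
            out = motif_enrichment(sites, target, background)
            sig += bool(out.loc["m", "p_bonferroni"] < 0.05)
        assert sig / n_seeds <= 0.15

    def test_overlapping_target_background_rejected(self):
        target = OCRSet([GenomicInterval("chr1", 0, 1000)])
        with pytest.raises(InputError):
            motif_enrichment([], target, target)

    def test_empty_background_rejected(self):
        target, _ = self._ocrs()
        with pytest.raises(InputError):
            motif_enrichment([], target, OCRSet([]))
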