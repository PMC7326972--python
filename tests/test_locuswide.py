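"""Locus scores, GSEA running sum, permutation null, enriched-gene calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncohist.genomic_io import BinnedTrack, GeneModel, GenomeAnnotation, Interval
from oncohist.locuswide import (
    EnrichmentResult,
    gene_locus_score,
    gsea_running_sum,
    locus_score_table,
    locuswide_enriched_genes,
    permutation_p,
    rank_by_enrichment,
)
from oncohist.occupancy import NormalizedRatioTrack, normalize_internal_control
from oncohist.synthetic import SimConfig, generate_genome, plant_truth, simulate_tracks


def _ratio_from_r(r_values, bin_size=100, sample_id="s", group="WT"):
    r_values = np.asarray(r_values, dtype=float)
    n = len(r_values)
    return NormalizedRatioTrack(
        bin_size=bin_size,
        chrom_sizes={"chr1": n * bin_size},
        r={"chr1": r_values},
        coverage={"chr1": np.ones(n)},
        sample_id=sample_id,
        group=group,
    )


class TestLocusScore:
    def test_constant_field_returns_constant(self):
        mut = [_ratio_from_r(np.full(100, 1.7), group="MUT")] * 2
        wt = [_ratio_from_r(np.zeros(100))] * 2
        g = GeneModel(Interval("chr1", 2000, 5000), "+", "g")
        assert gene_locus_score(g, mut, wt) == pytest.approx(1.7)

    def test_two_bin_weighted_mean_by_hand(self):
        # window spans exactly two bins with delta 1 and 3 -> score 2
        r = np.zeros(20)
        r[10], r[11] = 1.0, 3.0
        mut = [_ratio_from_r(r, group="MUT")] * 2
        wt = [_ratio_from_r(np.zeros(20))] * 2
        g = GeneModel(Interval("chr1", 1100, 1200), "+", "g")
        # upstream 100 -> window [1000, 1200) = bins 10, 11
        assert gene_locus_score(g, mut, wt, upstream=100) == pytest.approx(2.0)

    def test_strand_reflection_invariance(self):
        """Mirror-image tracks with mirrored genes give equal scores."""
        rng = np.random.default_rng(0)
        n = 100
        r = rng.normal(size=n)
        L = n * 100
        plus_gene = GeneModel(Interval("chr1", 3000, 6000), "+", "gp")
        # reflected coordinates: start' = L - end, end' = L - start
        minus_gene = GeneModel(Interval("chr1", L - 6000, L - 3000), "-", "gm")
        mut_f = [_ratio_from_r(r, group="MUT")] * 2
        wt_f = [_ratio_from_r(np.zeros(n))] * 2
        mut_rev = [_ratio_from_r(r[::-1].copy(), group="MUT")] * 2
        wt_rev = [_ratio_from_r(np.zeros(n))] * 2
        s_plus = gene_locus_score(plus_gene, mut_f, wt_f)
        s_minus = gene_locus_score(minus_gene, mut_rev, wt_rev)
        assert s_plus == pytest.approx(s_minus)

    def test_window_clipped_at_chromosome_edge_flagged(self):
        ann = GenomeAnnotation(
            chrom_sizes={"chr1": 10_000},
            genes=[GeneModel(Interval("chr1", 200, 2000), "+", "edge")],
        )
        mut = [_ratio_from_r(np.zeros(100), group="MUT")] * 2
        wt = [_ratio_from_r(np.zeros(100))] * 2
        table = locus_score_table(ann, mut, wt, upstream=1000)
        assert bool(table.loc["edge", "clipped"])
        assert table.loc["edge", "window_start"] == 0


class TestRanking:
    def test_descending_sort_oracle(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        table = pd.DataFrame(
            {"score": scores}, index=[f"g{i:02d}" for i in range(30)]
        )
        ranked = rank_by_enrichment(table)
        assert list(ranked["score"]) == sorted(scores, reverse=True)

    def test_ties_broken_lexicographically(self):
        table = pd.DataFrame({"score": [1.0, 1.0, 1.0]}, index=["c", "a", "b"])
        assert list(rank_by_enrichment(table).index) == ["a", "b", "c"]

    def test_input_order_invariance(self):
        table = pd.DataFrame(
            {"score": [3.0, 1.0, 2.0]}, index=["a", "b", "c"]
        )
        rev = table.iloc[::-1]
        assert list(rank_by_enrichment(table).index) == list(
            rank_by_enrichment(rev).index
        )


def brute_force_es(ranked, scores, gene_set, weight):
    """Independent running-sum walk, plain Python."""
    n = len(ranked)
    hits = [abs(s) ** weight if g in gene_set else 0.0 for g, s in zip(ranked, scores)]
    total = sum(hits)
    n_miss = n - sum(1 for g in ranked if g in gene_set)
    cur, best = 0.0, 0.0
    walk = []
    for g, h in zip(ranked, hits):
        if g in gene_set:
            cur += h / total
        else:
            cur -= 1.0 / n_miss
        walk.append(cur)
        # earliest rank wins ties in |deviation| up to float rounding
        if abs(cur) > abs(best) + 1e-9:
            best = cur
    return best, walk


class TestRunningSum:
    def test_singleton_top_gene_unweighted(self):
        genes = [f"g{i}" for i in range(10)]
        scores = np.linspace(5, -5, 10)
        res = gsea_running_sum(genes, scores, {"g0"}, weight=0.0)
        assert res.es == pytest.approx(1.0)

    def test_singleton_bottom_gene_hand_walk(self):
        genes = [f"g{i}" for i in range(5)]
        scores = np.linspace(2, -2, 5)
        res = gsea_running_sum(genes, scores, {"g4"}, weight=0.0)
        np.testing.assert_allclose(
            res.running_sum, [-0.25, -0.5, -0.75, -1.0, 0.0]
        )
        assert res.es == pytest.approx(-1.0)

    def test_walk_terminates_at_zero_unweighted(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            genes = [f"g{i}" for i in range(n)]
            scores = rng.normal(size=n)
            k = int(rng.integers(1, n))
            gs = set(rng.choice(genes, size=k, replace=False))
            res = gsea_running_sum(genes, np.sort(scores)[::-1], gs, weight=0.0)
            assert res.running_sum[-1] == pytest.approx(0.0, abs=1e-12)
            assert abs(res.es) <= 1.0 + 1e-12

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(5, 51))
            genes = [f"g{i:02d}" for i in range(n)]
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            gs = set(rng.choice(genes, size=k, replace=False))
            w = float(rng.choice([0.0, 1.0, 1.5]))
            res = gsea_running_sum(genes, scores, gs, weight=w)
            es_bf, walk_bf = brute_force_es(genes, scores, gs, w)
            np.testing.assert_allclose(res.running_sum, walk_bf, atol=1e-12)
            assert res.es == pytest.approx(es_bf, abs=1e-12)

    def test_empty_and_full_sets_rejected(self):
        genes = ["a", "b", "c"]
        scores = np.array([3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            gsea_running_sum(genes, scores, set())
        with pytest.raises(ValueError):
            gsea_running_sum(genes, scores, {"a", "b", "c"})


class TestPermutation:
    def test_extreme_observation_gets_minimum_p(self):
        genes = [f"g{i}" for i in range(50)]
        scores = np.linspace(10, -10, 50)
        gs = {f"g{i}" for i in range(5)}  # the 5 top-ranked genes
        res = permutation_p(genes, scores, gs, n_perm=200, seed=0)
        assert res.p_perm >= 1 / 201
        assert res.p_perm <= 0.05

    def test_p_lower_bound(self):
        genes = [f"g{i}" for i in range(30)]
        scores = np.linspace(3, -3, 30)
        res = permutation_p(genes, scores, {"g0", "g1"}, n_perm=50, seed=1)
        assert res.p_perm >= 1 / 51

    def test_same_seed_identical_p(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        scores = np.sort(rng.normal(size=40))[::-1]
        gs = set(rng.choice(genes, 6, replace=False))
        a = permutation_p(genes, scores, gs, n_perm=100, seed=7)
        b = permutation_p(genes, scores, gs, n_perm=100, seed=7)
        assert a.p_perm == b.p_perm

    def test_uniform_under_random_sets(self):
        """Calibration: p over 500 random gene sets is approximately uniform."""
        rng = np.random.default_rng(5)
        N, k = 200, 10
        genes = [f"g{i}" for i in range(N)]
        ps = []
        for rep in range(500):
            scores = np.sort(rng.normal(size=N))[::-1]
            gs = set(rng.choice(genes, size=k, replace=False))
            ps.append(permutation_p(genes, scores, gs, n_perm=99, seed=rep).p_perm)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestEnrichedGenes:
    def _tracks(self, config):
        ann = generate_genome(config)
        truth = plant_truth(ann, config)
        tracks = simulate_tracks(ann, truth, config)
        ratio = {}
        for clone, grp in (
            (c, g) for g, cs in config.clone_names.items() for c in cs
        ):
            ratio[clone] = normalize_internal_control(
                tracks["flag"][clone], tracks["h2a"][clone], group=grp
            )
        mut = [t for t in ratio.values() if t.group == "MUT"]
        wt = [t for t in ratio.values() if t.group == "WT"]
        return ann, truth, mut, wt

    def test_identical_groups_empty(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__, "flag_enrichment_log2": 0.0})
        ann, truth, mut, wt = self._tracks(cfg)
        enriched, _ = locuswide_enriched_genes(ann, mut, wt)
        assert len(enriched) <= 0.01 * len(ann)

    def test_planted_recovery(self, small_config):
        ann, truth, mut, wt = self._tracks(small_config)
        enriched, _ = locuswide_enriched_genes(ann, mut, wt)
        tp = len(enriched & truth.flag_genes)
        assert tp / len(truth.flag_genes) >= 0.9
        assert tp / len(enriched) >= 0.9

    def test_monotone_in_alpha(self, small_config):
        ann, truth, mut, wt = self._tracks(small_config)
        sets = [
            locuswide_enriched_genes(ann, mut, wt, alpha=a)[0]
            for a in (1e-12, 0.01, 0.05, 0.5)
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger
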