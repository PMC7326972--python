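"""Peak categorization, shuffled-null enrichment and ATAC co-localization."""

import numpy as np
import pytest

from oncohist.annotation import (
    AnnotationIndex,
    assign_categories,
    assign_category,
    atac_colocalization,
    category_counts,
    chi_square_distribution_test,
    peak_distribution_enrichment,
    promoter_expression_crosstab,
    shuffle_peaks,
)
from oncohist.genomic_io import GeneModel, GenomeAnnotation, Interval


class TestAssignCategory:
    def test_peak_in_promoter(self, toy_annotation):
        # gplus TSS at 2000; promoter window [1000, 3000)
        assert assign_category(Interval("chr1", 1100, 1200), toy_annotation) == "promoter"

    def test_peak_nowhere(self, toy_annotation):
        assert assign_category(Interval("chr1", 4500, 4600), toy_annotation) == "intergenic"

    def test_precedence_promoter_over_gene_body(self, toy_annotation):
        # straddles promoter [1000,3000) and gene body [2000,4000)
        peak = Interval("chr1", 2900, 3500)
        assert assign_category(peak, toy_annotation) == "promoter"
        # brute-force overlap sets confirm it touches both
        prom = Interval("chr1", 1000, 3000)
        body = Interval("chr1", 2000, 4000)
        assert peak.overlaps(prom) and peak.overlaps(body)

    def test_gene_body_only(self, toy_annotation):
        assert assign_category(Interval("chr1", 3200, 3400), toy_annotation) == "gene_body"

    def test_minus_strand_promoter_extends_rightward(self, toy_annotation):
        # gminus TSS at 7999; upstream is rightward, window ~ [7000, 9000)
        assert assign_category(Interval("chr1", 8500, 8600), toy_annotation) == "promoter"

    def test_every_peak_gets_exactly_one_category(self, small_annotation):
        rng = np.random.default_rng(4)
        index = AnnotationIndex.build(small_annotation)
        peaks = []
        for _ in range(300):
            c = f"chr{rng.integers(1, 3)}"
            s = int(rng.integers(0, small_annotation.chrom_sizes[c] - 400))
            peaks.append(Interval(c, s, s + 400))
        counts = category_counts(index, peaks)
        assert counts.sum() == len(peaks)


class TestShuffle:
    def test_length_multiset_and_chromosome_conserved(self, small_annotation):
        rng = np.random.default_rng(0)
        peaks = [
            Interval(f"chr{rng.integers(1, 3)}", s := int(rng.integers(0, 10_000)),
                     s + int(rng.integers(200, 2000)))
            for _ in range(40)
        ]
        shuffles = shuffle_peaks(peaks, small_annotation.chrom_sizes, 5, seed=1)
        key = sorted((p.chrom, p.length) for p in peaks)
        for sh in shuffles:
            assert sorted((p.chrom, p.length) for p in sh) == key

    def test_same_seed_identical(self, small_annotation):
        peaks = [Interval("chr1", 0, 500), Interval("chr2", 100, 900)]
        a = shuffle_peaks(peaks, small_annotation.chrom_sizes, 3, seed=9)
        b = shuffle_peaks(peaks, small_annotation.chrom_sizes, 3, seed=9)
        assert a == b

    def test_peak_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            shuffle_peaks([Interval("chr1", 0, 2000)], {"chr1": 1000}, 1, seed=0)

    def test_promoter_fraction_matches_binomial_expectation(self):
        # genome where promoters cover a known fraction
        genes = [
            GeneModel(Interval("chr1", s, s + 2000), "+", f"g{i}")
            for i, s in enumerate(range(5000, 100_000, 10_000))
        ]
        ann = GenomeAnnotation(chrom_sizes={"chr1": 100_000}, genes=genes)
        index = AnnotationIndex.build(ann, 1000, 1000)
        ps, pe = index.promoters["chr1"]
        prom_frac = (pe - ps).sum() / 100_000
        peaks = [Interval("chr1", i, i + 1) for i in range(100)]
        shuffles = shuffle_peaks(peaks, ann.chrom_sizes, 1000, seed=5)
        fracs = []
        for sh in shuffles:
            starts = np.array([p.start for p in sh])
            cat = assign_categories(index, "chr1", starts, starts + 1)
            fracs.append((cat == 0).mean())
        assert np.mean(fracs) == pytest.approx(prom_frac, abs=0.03)


class TestChiSquare:
    def test_observed_equals_expected(self):
        res = chi_square_distribution_test(
            np.array([10, 20, 30]), [np.array([10, 20, 30])] * 4
        )
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_formula(self):
        res = chi_square_distribution_test(
            np.array([50, 30, 20]), [np.array([40, 40, 20])]
        )
        assert res.chi2 == pytest.approx(5.0)
        assert res.df == 2
        assert res.p == pytest.approx(0.0821, abs=2e-4)

    def test_expected_rescaled_to_observed_total(self):
        res = chi_square_distribution_test(
            np.array([50, 30, 20]), [np.array([80, 80, 40])]
        )
        assert res.expected.sum() == pytest.approx(100.0)

    def test_zero_expected_category_errors(self):
        with pytest.raises(ValueError, match="more shuffles"):
            chi_square_distribution_test(
                np.array([5, 5, 5]), [np.array([5, 5, 0])]
            )

    def test_null_calibration_small(self, small_annotation):
        """Uniformly placed peaks rejected at ~alpha; small-scale check."""
        rng = np.random.default_rng(21)
        index = AnnotationIndex.build(small_annotation)
        chroms = sorted(small_annotation.chrom_sizes)
        rej = 0
        n_data = 100
        for _ in range(n_data):
            obs = np.zeros(3, dtype=int)
            cs = rng.integers(0, 2, size=100)
            starts_by = {}
            for ci, c in enumerate(chroms):
                k = int((cs == ci).sum())
                L = small_annotation.chrom_sizes[c]
                starts = rng.integers(0, L - 500, size=k)
                starts_by[c] = starts
                obs += np.bincount(
                    assign_categories(index, c, starts, starts + 500), minlength=3
                )
            shufs = []
            for _ in range(200):
                cnt = np.zeros(3, dtype=int)
                for ci, c in enumerate(chroms):
                    k = len(starts_by[c])
                    L = small_annotation.chrom_sizes[c]
                    starts = rng.integers(0, L - 500, size=k)
                    cnt += np.bincount(
                        assign_categories(index, c, starts, starts + 500), minlength=3
                    )
                shufs.append(cnt)
            if chi_square_distribution_test(obs, shufs).p < 0.05:
                rej += 1
        assert rej / n_data <= 0.12  # loose bound at this replicate count


class TestColocalization:
    def test_identical_sets_fraction_one(self):
        ivs = [Interval("chr1", i * 1000, i * 1000 + 200) for i in range(10)]
        res = atac_colocalization(ivs, list(ivs))
        assert res.fraction == 1.0

    def test_disjoint_sets_fraction_zero(self):
        a = [Interval("chr1", 0, 100)]
        b = [Interval("chr1", 200, 300)]
        assert atac_colocalization(a, b).fraction == 0.0

    def test_sweep_equals_all_pairs_brute_force(self):
        rng = np.random.default_rng(8)
        def rand_ivs(n):
            out = []
            for _ in range(n):
                c = f"chr{rng.integers(1, 3)}"
                s = int(rng.integers(0, 50_000))
                out.append(Interval(c, s, s + int(rng.integers(50, 2000))))
            return out
        peaks, atac = rand_ivs(200), rand_ivs(200)
        res = atac_colocalization(peaks, atac)
        brute = sum(1 for p in peaks if any(p.overlaps(a) for a in atac))
        assert res.n_colocalized == brute


class TestCrosstab:
    def test_empty_up_set(self, toy_annotation):
        peaks = [Interval("chr1", 1100, 1300)]
        res = promoter_expression_crosstab(peaks, toy_annotation, set())
        assert res["n_promoter_genes"] == 1
        assert res["n_also_up"] == 0

    def test_saturated_up_set(self, toy_annotation):
        peaks = [Interval("chr1", 1100, 1300), Interval("chr1", 8100, 8300)]
        res = promoter_expression_crosstab(
            peaks, toy_annotation, {"gplus", "gminus"}
        )
        assert res["n_promoter_genes"] == res["n_also_up"] == 2

    def test_planted_truth_crosstab(self, small_annotation, small_truth, small_config):
        # peaks exactly at promoters of flag genes; up set = planted up genes
        peaks = []
        for g in small_annotation.genes:
            if g.gene_id in small_truth.flag_genes:
                w = g.promoter_window(200, 200, small_annotation.chrom_sizes[g.chrom])
                peaks.append(Interval(w.chrom, w.start, w.end))
        res = promoter_expression_crosstab(
            peaks, small_annotation, small_truth.up_genes
        )
        assert set(res["up_promoter_genes"]) >= small_truth.flag_genes


def test_full_enrichment_on_promoter_concentrated_peaks(small_annotation):
    # all peaks at promoters -> distribution wildly non-uniform
    peaks = []
    for g in small_annotation.genes[:50]:
        t = g.tss
        peaks.append(Interval(g.chrom, max(t - 100, 0), t + 100))
    res = peak_distribution_enrichment(peaks, small_annotation,
                                       n_shuffles=200, seed=3)
    assert res.observed[0] == 50
    assert res.p < 1e-10
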