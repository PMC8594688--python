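"""Global group comparison, fold enrichment, Fisher overlap, gain-vs-loss
comparison and the candidate-gene table."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methgwas.core import GeneRecord, GenomicInterval, ValidationError, merge_intervals
from methgwas.integration import (
    candidate_gene_table,
    element_fold_enrichment,
    gain_loss_comparison,
    global_methylation_test,
    overlap_fisher,
)
from methgwas.simulate import (
    PlantedDmrTile,
    SimulationDesign,
    default_layout,
    simulate_methylomes,
)


class TestGlobalMethylationTest:
    def test_identical_groups_null(self, layout, make_sample_factory):
        rows = [("chr1", 100 * i, 5, 10) for i in range(20)]
        a = make_sample_factory(layout, rows, "a")
        b = make_sample_factory(layout, rows, "b")
        t, p, diff = global_methylation_test([a], [b])
        assert (t, p, diff) == (0.0, 1.0, 0.0)

    def test_symmetric_differences_cancel(self, layout, make_sample_factory):
        a = make_sample_factory(layout, [("chr1", 0, 6, 10), ("chr1", 100, 4, 10)], "a")
        b = make_sample_factory(layout, [("chr1", 0, 5, 10), ("chr1", 100, 5, 10)], "b")
        t, p, diff = global_methylation_test([a], [b])
        assert t == pytest.approx(0.0)
        assert diff == pytest.approx(0.0)

    def test_planted_global_shift_detected(self):
        # +5-point shift in group 1 across ~1e4 loci at coverage 10
        layout = default_layout(1, 1_000_000)
        d1 = SimulationDesign(layout=layout, baseline_meth=0.80, n_samples_per_group=1, seed=30)
        d2 = SimulationDesign(layout=layout, baseline_meth=0.75, n_samples_per_group=1, seed=30)
        a, _ = simulate_methylomes(d1)
        b, _ = simulate_methylomes(d2)
        t, p, diff = global_methylation_test([a[0]], [b[0]])
        assert p < 1e-10
        assert 0.03 < diff < 0.07

    def test_too_few_common_loci_rejected(self, layout, make_sample_factory):
        a = make_sample_factory(layout, [("chr1", 0, 5, 10)], "a")
        b = make_sample_factory(layout, [("chr2", 0, 5, 10)], "b")
        with pytest.raises(ValidationError):
            global_methylation_test([a], [b])


class TestElementFoldEnrichment:
    def test_whole_genome_element_fold_one(self, layout):
        features = merge_intervals([GenomicInterval("chr1", 100, 600)])
        genome = merge_intervals(
            [GenomicInterval(c, 0, l) for c, l in layout.lengths.items()]
        )
        fold = element_fold_enrichment(features, genome, layout.total_bp)
        assert fold == pytest.approx(1.0)

    def test_feature_inside_ten_percent_element(self):
        # element covers 10% of a 1-Mb genome; features entirely inside
        features = merge_intervals([GenomicInterval("chr1", 10_000, 20_000)])
        element = merge_intervals([GenomicInterval("chr1", 0, 100_000)])
        assert element_fold_enrichment(features, element, 1_000_000) == pytest.approx(10.0)

    def test_no_overlap_fold_zero(self):
        features = merge_intervals([GenomicInterval("chr1", 0, 100)])
        element = merge_intervals([GenomicInterval("chr1", 500, 600)])
        assert element_fold_enrichment(features, element, 1_000) == 0.0

    def test_scale_invariance(self):
        f1 = merge_intervals([GenomicInterval("chr1", 100, 300)])
        e1 = merge_intervals([GenomicInterval("chr1", 200, 800)])
        f2 = merge_intervals([GenomicInterval("chr1", 200, 600)])
        e2 = merge_intervals([GenomicInterval("chr1", 400, 1_600)])
        assert element_fold_enrichment(f1, e1, 10_000) == pytest.approx(
            element_fold_enrichment(f2, e2, 20_000)
        )

    def test_random_features_fold_near_one(self):
        rng = np.random.default_rng(4)
        folds = []
        for _ in range(10):
            starts = rng.choice(990_000, size=200, replace=False)
            feats = merge_intervals(
                [GenomicInterval("chr1", int(s), int(s) + 500) for s in starts]
            )
            estarts = rng.choice(900_000, size=50, replace=False)
            elems = merge_intervals(
                [GenomicInterval("chr1", int(s), int(s) + 5_000) for s in estarts]
            )
            folds.append(element_fold_enrichment(feats, elems, 1_000_000))
        assert abs(np.mean(folds) - 1.0) < 0.1

    def test_empty_features_rejected(self):
        with pytest.raises(ValidationError):
            element_fold_enrichment(
                merge_intervals([]), merge_intervals([GenomicInterval("chr1", 0, 10)]), 100
            )


def enum_fisher_upper(n_total, n_a, n_b, n_shared):
    total = math.comb(n_total, n_b)
    acc = 0
    for x in range(n_shared, min(n_a, n_b) + 1):
        acc += math.comb(n_a, x) * math.comb(n_total - n_a, n_b - x)
    return acc / total


class TestOverlapFisher:
    def test_matches_enumeration_small_populations(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n_total = int(rng.integers(10, 501))
            n_a = int(rng.integers(1, n_total + 1))
            n_b = int(rng.integers(1, n_total + 1))
            lo = max(0, n_a + n_b - n_total)
            n_shared = int(rng.integers(lo, min(n_a, n_b) + 1))
            table = overlap_fisher(n_total, n_a, n_b, n_shared)
            assert table.p == pytest.approx(
                enum_fisher_upper(n_total, n_a, n_b, n_shared), rel=1e-9, abs=1e-300
            )

    def test_central_overlap_p_near_half(self):
        n_total, n_a, n_b = 10_000, 800, 600
        n_shared = round(n_a * n_b / n_total)
        table = overlap_fisher(n_total, n_a, n_b, n_shared)
        assert 0.3 <= table.p <= 0.7

    def test_all_tiles_in_set_a_p_one(self):
        table = overlap_fisher(100, 100, 30, 30)
        assert table.p == pytest.approx(1.0)

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValidationError):
            overlap_fisher(100, 60, 60, 10)  # union would exceed total
        with pytest.raises(ValidationError):
            overlap_fisher(100, 5, 5, 6)

    def test_expected_overlap_reported(self):
        table = overlap_fisher(1_000, 100, 50, 10)
        assert table.expected == pytest.approx(5.0)


class TestGainLossComparison:
    def test_identical_panels_p_one(self):
        w, p = gain_loss_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_small_sample_example(self):
        # fully separated ranks: 2 of C(6,3)=20 orderings as extreme
        w, p = gain_loss_comparison([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            gain_loss_comparison([1.0, np.nan], [1.0, 2.0])

    def test_planted_gain_enrichment_usually_significant(self):
        # gain features carry delta=2 signal, loss features none; the
        # rank-sum comparison of -log10 p panels should usually reject
        from methgwas.gwas_enrichment import cyclic_permutation_test
        from methgwas.simulate import simulate_gwas

        layout = default_layout(1, 50_000_000)
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            enriched = merge_intervals(
                [GenomicInterval("chr1", 5_000_000 + 3_000_000 * i, 5_400_000 + 3_000_000 * i)
                 for i in range(5)],
                layout=layout,
            )
            stats, _ = simulate_gwas(layout, 20_000, enriched, delta=2.0, seed=seed)
            gain_p, loss_p = [], []
            rng = np.random.default_rng(seed)
            for i in range(5):
                gain_feat = merge_intervals(
                    [GenomicInterval("chr1", 5_000_000 + 3_000_000 * i, 5_400_000 + 3_000_000 * i)]
                )
                start = int(rng.integers(20_000_000, 45_000_000))
                loss_feat = merge_intervals([GenomicInterval("chr1", start, start + 400_000)])
                gain_p.append(cyclic_permutation_test(stats, gain_feat, 200, rng).p_emp)
                loss_p.append(cyclic_permutation_test(stats, loss_feat, 200, rng).p_emp)
            _, p = gain_loss_comparison(-np.log10(gain_p), -np.log10(loss_p))
            hits += p < 0.05
        assert hits >= 0.8 * n_seeds


class TestCandidateGeneTable:
    def results_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "q", "diff"]
        )

    def fixture(self, snp_p=1e-7):
        # gene on + strand at [10_000, 30_000); promoter [8_000, 10_000);
        # DMR tile [8_500, 9_000) inside the promoter, gain in both
        gene = GeneRecord("geneA", GenomicInterval("chr1", 10_000, 30_000), "+")
        age = self.results_frame([("chr1", 8_500, 9_000, 0.001, 12.0)])
        scr = self.results_frame([("chr1", 8_500, 9_000, 0.002, 8.0)])
        t = sps.chi2.isf(snp_p, df=1) ** 0.5
        gwas = pd.DataFrame(
            {
                "trait": "scr",
                "chrom": "chr1",
                "pos": [15_000],
                "b": [t],
                "se": [1.0],
            }
        )
        gwas["t2"] = (gwas["b"] / gwas["se"]) ** 2
        return age, scr, [gene], {"scr": gwas}

    def test_planted_gain_gain_gene_with_suggestive_snp(self):
        age, scr, genes, gwas = self.fixture(snp_p=1e-7)
        rows = candidate_gene_table(age, scr, genes, gwas)
        assert len(rows) == 1
        row = rows[0]
        assert row.gene_id == "geneA"
        assert row.trait == "scr"
        assert row.top_snp_pos == 15_000
        assert row.top_snp_p == pytest.approx(1e-7, rel=1e-6)

    def test_snp_threshold_is_strict(self):
        age, scr, genes, gwas = self.fixture(snp_p=1e-4)
        assert candidate_gene_table(age, scr, genes, gwas) == []

    def test_no_shared_dmrs_empty(self):
        _, _, genes, gwas = self.fixture()
        age = self.results_frame([("chr1", 8_500, 9_000, 0.001, 12.0)])
        scr = self.results_frame([("chr1", 20_000, 20_500, 0.001, 12.0)])
        assert candidate_gene_table(age, scr, genes, gwas) == []

    def test_loss_in_one_contrast_excluded(self):
        age, scr, genes, gwas = self.fixture()
        scr = scr.assign(diff=-8.0)
        assert candidate_gene_table(age, scr, genes, gwas) == []

    def test_snp_outside_window_excluded(self):
        age, scr, genes, gwas = self.fixture()
        gwas["scr"] = gwas["scr"].assign(pos=900_000)
        assert candidate_gene_table(age, scr, genes, gwas, snp_window_bp=250_000) == []
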