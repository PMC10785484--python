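"""Synthetic panel / cohort / pileup generator behaviour."""

import numpy as np
import pytest

from haplopass.simulate import (
    HaplotypePanel,
    inject_switch_errors,
    simulate_cohort,
    simulate_panel,
    simulate_pileup,
    subset_panel,
    thin_pileup,
)


class TestSimulatePanel:
    def test_no_variation_when_rates_zero(self):
        panel = simulate_panel(2, 4, 50, 10_000, founder_div=0.0, mutation_rate=0.0, seed=1)
        assert np.all(panel.alleles == panel.alleles[0])
        assert set(np.unique(panel.panel_af)) <= {0.0, 1.0}

    def test_haplotypes_equal_founders_without_recomb_or_mutation(self):
        panel = simulate_panel(
            3, 4, 80, 10_000, founder_div=0.3, mutation_rate=0.0,
            recomb_switch_rate=0.0, seed=2,
        )
        for b in range(3):
            block = panel.alleles[panel.breed_label == f"breed{b}"]
            assert np.all(block == block[0])

    def test_deterministic_under_fixed_seed(self):
        a = simulate_panel(2, 4, 50, 100_000, seed=9)
        b = simulate_panel(2, 4, 50, 100_000, seed=9)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)

    def test_invariants(self, small_panel):
        small_panel.validate()
        assert np.all(np.diff(small_panel.positions) > 0)
        assert small_panel.n_haplotypes % 2 == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_breeds=2, haps_per_breed=3, n_sites=10, chrom_length_bp=100),
            dict(n_breeds=2, haps_per_breed=4, n_sites=200, chrom_length_bp=100),
            dict(n_breeds=2, haps_per_breed=4, n_sites=1, chrom_length_bp=100),
        ],
    )
    def test_rejects_bad_arguments(self, kwargs):
        with pytest.raises(ValueError):
            simulate_panel(**kwargs, seed=0)


class TestSubsetPanel:
    def test_full_subset_is_identity(self, small_panel):
        sub = subset_panel(small_panel, "breed0", small_panel.n_haplotypes // 2)
        assert np.array_equal(sub.alleles, small_panel.alleles)
        assert np.allclose(sub.panel_af, small_panel.panel_af)

    def test_target_depleted_keeps_at_most_one_target_diploid(self, small_panel):
        sub = subset_panel(small_panel, "breed0", 5, include_target=False, seed=3)
        n_target = np.sum(sub.breed_label[::2] == "breed0")
        assert n_target <= 1
        assert sub.n_haplotypes == 10

    def test_monomorphic_columns_stay_binary(self, small_panel):
        sub = subset_panel(small_panel, "breed0", 4, seed=1)
        mono = (sub.panel_af == 0) | (sub.panel_af == 1)
        assert np.all(np.isin(sub.panel_af[mono], [0.0, 1.0]))

    def test_missing_target_breed_raises(self, small_panel):
        with pytest.raises(ValueError, match="absent"):
            subset_panel(small_panel, "nonesuch", 4, include_target=True)

    def test_pairs_kept_together(self, small_panel):
        sub = subset_panel(small_panel, "breed0", 6, seed=5)
        assert np.all(sub.breed_label[::2] == sub.breed_label[1::2])


class TestSimulateCohort:
    def test_haplotypes_subset_of_panel_when_rates_zero(self, small_panel):
        cohort = simulate_cohort(
            small_panel, 12, 3, mosaic_switch_rate=0.0, private_allele_rate=0.0,
            seed=7,
        )
        # exclude the causal site, whose genotypes are overwritten to enforce
        # the case count
        keep = np.ones(small_panel.n_sites, bool)
        keep[cohort.causal_site] = False
        panel_set = {row[keep].tobytes() for row in small_panel.alleles}
        for i in range(cohort.n_individuals):
            assert cohort.hapA[i][keep].tobytes() in panel_set
            assert cohort.hapB[i][keep].tobytes() in panel_set

    def test_case_count_and_recessive_phenotype(self, small_panel):
        truth = simulate_cohort(small_panel, 30, 6, seed=11)
        assert truth.phenotype.sum() == 6
        g = truth.genotypes[:, truth.causal_site]
        assert np.all(g[truth.phenotype == 1] == 2)
        assert np.all(g[truth.phenotype == 0] < 2)
        truth.validate()

    def test_phenotype_consistency_across_seeds(self, small_panel):
        for seed in range(5):
            simulate_cohort(small_panel, 10, 2, seed=seed).validate()

    def test_private_mask_density_matches_rate(self):
        panel = simulate_panel(3, 6, 5000, 20_000_000, seed=3)
        rate = 0.01
        truth = simulate_cohort(panel, 30, 6, private_allele_rate=rate, seed=4)
        density = truth.private_mask.mean()
        n = truth.private_mask.size
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(density - rate) < 5 * se + 1.0 / n

    def test_causal_maf_window_unsatisfiable_raises(self):
        panel = simulate_panel(2, 4, 50, 10_000, founder_div=0.0, mutation_rate=0.0, seed=1)
        with pytest.raises(ValueError, match="MAF"):
            simulate_cohort(panel, 10, 2, seed=0)


class TestPileups:
    def test_no_alt_reads_without_error_or_alt_alleles(self, small_cohort):
        hom_ref = np.zeros_like(small_cohort.hapA)
        ref_truth = type(small_cohort)(
            hapA=hom_ref, hapB=hom_ref,
            phenotype=small_cohort.phenotype, sex=small_cohort.sex,
            causal_site=small_cohort.causal_site,
            private_mask=small_cohort.private_mask,
        )
        pu = simulate_pileup(ref_truth, 5.0, epsilon=1e-12, seed=1)
        assert pu.alt_count.sum() == 0

    def test_grand_mean_depth_matches_lambda(self, small_cohort):
        pu = simulate_pileup(small_cohort, 43.5, seed=2)
        n_cells = pu.depth.size
        # CLT bound: se of the grand mean of Poisson(43.5) cells
        se = np.sqrt(43.5 / n_cells)
        assert abs(pu.depth.mean() - 43.5) < 5 * se

    def test_depressed_segment_halves_depth_and_is_detectable(self, small_cohort):
        M = small_cohort.hapA.shape[1]
        profile = np.ones(M)
        profile[:60] = 0.5
        pu = simulate_pileup(small_cohort, 9.6, region_profile=profile, seed=3)
        seg = pu.depth[:, :60].mean()
        rest = pu.depth[:, 60:].mean()
        assert seg < 0.6 * rest
        from scipy.stats import wilcoxon

        p = wilcoxon(pu.depth[:, :60].mean(axis=1) - pu.depth.mean(axis=1)).pvalue
        assert p < 0.05

    def test_determinism(self, small_cohort):
        a = simulate_pileup(small_cohort, 3.8, seed=5)
        b = simulate_pileup(small_cohort, 3.8, seed=5)
        assert np.array_equal(a.ref_count, b.ref_count)
        assert np.array_equal(a.alt_count, b.alt_count)


class TestThinning:
    def test_retain_all_and_none(self, small_cohort):
        pu = simulate_pileup(small_cohort, 10.0, seed=1)
        full = thin_pileup(pu, 1.0, seed=2)
        assert np.array_equal(full.ref_count, pu.ref_count)
        empty = thin_pileup(pu, 0.0, seed=2)
        assert empty.depth.sum() == 0

    def test_expected_depth_after_thinning(self, small_cohort):
        pu = simulate_pileup(small_cohort, 43.5, seed=3)
        thinned = thin_pileup(pu, 0.4, seed=4)
        assert abs(thinned.depth.mean() - 17.4) / 17.4 < 0.02

    def test_composition_matches_single_thinning(self, small_cohort):
        # thin(thin(P, a), b) should be distributed as thin(P, ab):
        # compare means and variances over >= 1e4 cells
        pu = simulate_pileup(small_cohort, 30.0, seed=5)
        two = thin_pileup(thin_pileup(pu, 0.5, seed=6), 0.4, seed=7)
        one = thin_pileup(pu, 0.2, seed=8)
        for a, b in [(two.depth, one.depth)]:
            assert a.size >= 1e4 / 3
            assert abs(a.mean() - b.mean()) < 0.1
            assert abs(a.var() - b.var()) / b.var() < 0.15


class TestSwitchErrors:
    def test_zero_rate_is_identity(self, small_cohort):
        a, b = inject_switch_errors(small_cohort.hapA, small_cohort.hapB, 0.0, seed=1)
        assert np.array_equal(a, small_cohort.hapA)
        assert np.array_equal(b, small_cohort.hapB)

    def test_genotypes_preserved(self, small_cohort):
        a, b = inject_switch_errors(small_cohort.hapA, small_cohort.hapB, 0.1, seed=2)
        assert np.array_equal(a + b, small_cohort.genotypes)
        assert not np.array_equal(a, small_cohort.hapA)
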