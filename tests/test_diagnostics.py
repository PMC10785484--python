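"""Region sampling, haplotype counting, depth tests, regressions."""

import numpy as np
import pandas as pd
import pytest

from haplopass.diagnostics import (
    correlation_suite,
    count_region_haplotypes,
    ols_regress,
    region_depth_wilcoxon,
    sample_regions,
    window_metrics,
)
from haplopass.simulate import ReadPileup, simulate_pileup

from _oracles import distinct_strings, wilcoxon_exact


def _phased(strings):
    """Build an (N=1, M, 2) phased array from two allele strings."""
    a, b = strings
    return np.stack([np.array(list(a), int), np.array(list(b), int)], axis=-1)[None].astype(np.int8)


class TestSampleRegions:
    def test_exact_variant_count_and_determinism(self):
        pos = np.sort(np.random.default_rng(0).choice(10**6, 500, replace=False)) + 1
        r1 = sample_regions(pos, 50, 100, seed=3)
        r2 = sample_regions(pos, 50, 100, seed=3)
        assert np.array_equal(r1.start_index, r2.start_index)
        assert np.all(r1.end_index - r1.start_index == 100)
        assert np.all(r1.end_index <= 500)

    def test_whole_chromosome_region(self):
        pos = np.arange(1, 101)
        r = sample_regions(pos, 5, 100, seed=1)
        assert np.all(r.start_index == 0)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            sample_regions(np.arange(1, 50), 5, 100)


class TestCountRegionHaplotypes:
    def test_identical_data_with_het_site_gives_two(self):
        block = _phased(("0101", "0011"))
        counts = count_region_haplotypes([block] * 5, np.arange(4), 0)
        assert counts == 2

    def test_identical_fully_homozygous_gives_one(self):
        block = _phased(("0101", "0101"))
        assert count_region_haplotypes([block] * 5, np.arange(4), 0) == 1

    def test_single_genotype_change_gives_three(self):
        # one depth calls 0|0 where the rest call 0|1: one haplotype string
        # still matches, so three distinct strings emerge
        base = _phased(("0101", "0011"))
        altered = base.copy()
        altered[0, 3] = [1, 0]  # 1|1 -> 1|0: haplotype A unchanged
        assert count_region_haplotypes([base] * 4 + [altered], np.arange(4), 0) == 3

    def test_matches_set_of_strings_oracle(self, rng):
        for _ in range(30):
            n_depths = int(rng.integers(1, 6))
            m = int(rng.integers(2, 13))
            blocks = [
                rng.integers(0, 2, (1, m, 2)).astype(np.int8) for _ in range(n_depths)
            ]
            count = count_region_haplotypes(blocks, np.arange(m), 0)
            oracle = distinct_strings(
                [b[0, :, a] for b in blocks for a in (0, 1)]
            )
            assert count == oracle

    def test_at_most_two_for_identical_inputs(self, rng):
        for _ in range(10):
            block = rng.integers(0, 2, (2, 8, 2)).astype(np.int8)
            c = count_region_haplotypes([block] * 5, np.arange(8), 1)
            assert c <= 2

    def test_novel_single_allele_flip_adds_exactly_one(self, rng):
        blocks = [rng.integers(0, 2, (1, 10, 2)).astype(np.int8) for _ in range(4)]
        before = count_region_haplotypes(blocks, np.arange(10), 0)
        flipped = [b.copy() for b in blocks]
        flipped[2][0, 5, 0] ^= 1
        new_string = tuple(flipped[2][0, :, 0].tolist())
        existing = {tuple(b[0, :, a].tolist()) for b in blocks for a in (0, 1)}
        after = count_region_haplotypes(flipped, np.arange(10), 0)
        old_string = tuple(blocks[2][0, :, 0].tolist())
        others = {tuple(b[0, :, a].tolist())
                  for i, b in enumerate(blocks) for a in (0, 1) if (i, a) != (2, 0)}
        if new_string not in existing and old_string in others:
            assert after == before + 1

    def test_restrict_mode_drops_masked_positions(self):
        from haplopass.impute import ImputedCallset

        phased = _phased(("0101", "0011"))
        missing = np.zeros((1, 4), bool)
        missing[0, 3] = True
        cs = ImputedCallset(
            phased=phased, gp=np.zeros((1, 4, 3)), dosage=np.zeros((1, 4)),
            info=np.zeros(4), missing=missing, panel_af_used=np.zeros(4),
            positions=np.arange(1, 5),
        )
        clean = ImputedCallset(
            phased=phased, gp=np.zeros((1, 4, 3)), dosage=np.zeros((1, 4)),
            info=np.zeros(4), missing=np.zeros((1, 4), bool),
            panel_af_used=np.zeros(4), positions=np.arange(1, 5),
        )
        # restrict: masked column dropped for all depths -> strings agree
        assert count_region_haplotypes([cs, clean], np.arange(4), 0, mode="restrict") == 2
        # symbol: the masked cell differentiates the two datasets
        assert count_region_haplotypes([cs, clean], np.arange(4), 0, mode="symbol") == 4


class TestRegionDepthWilcoxon:
    def test_matches_exact_enumeration_oracle(self, rng):
        for n in (6, 8, 10):
            for trial in range(5):
                region = rng.normal(10, 2, size=(n, 4))
                chrom = region + rng.normal(0.5, 1.0, size=(n, 4))
                depth = np.concatenate([region, chrom], axis=1).round(3)
                pu = ReadPileup(
                    ref_count=np.maximum(depth, 0).astype(np.int64),
                    alt_count=np.zeros_like(depth, dtype=np.int64),
                    epsilon=0.001, lambda_target=10.0,
                )
                p = region_depth_wilcoxon(pu, np.arange(4))
                diff = pu.depth[:, :4].mean(axis=1) - pu.depth.mean(axis=1)
                if np.all(diff == 0):
                    assert p == 1.0
                else:
                    assert p == pytest.approx(wilcoxon_exact(diff), abs=1e-9)

    def test_identical_pairs_give_one(self):
        depth = np.tile(np.arange(1, 9)[:, None], (1, 10)).astype(np.int64)
        pu = ReadPileup(ref_count=depth, alt_count=np.zeros_like(depth),
                        epsilon=0.001, lambda_target=5.0)
        assert region_depth_wilcoxon(pu, np.arange(10)) == 1.0

    def test_depressed_region_detected(self, small_cohort):
        M = small_cohort.hapA.shape[1]
        profile = np.ones(M)
        profile[:50] = 0.5
        hits = 0
        for seed in range(20):
            pu = simulate_pileup(small_cohort, 9.6, region_profile=profile, seed=seed)
            if region_depth_wilcoxon(pu, np.arange(50)) < 0.05:
                hits += 1
        assert hits >= 19

    def test_too_few_individuals_rejected(self):
        depth = np.ones((3, 10), dtype=np.int64)
        pu = ReadPileup(ref_count=depth, alt_count=np.zeros_like(depth),
                        epsilon=0.001, lambda_target=1.0)
        with pytest.raises(ValueError):
            region_depth_wilcoxon(pu, np.arange(5))


class TestOlsRegress:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        out = ols_regress(2 * x, pd.DataFrame({"x": x}))
        assert out["table"].loc["x", "coef"] == pytest.approx(2.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_categorical_treatment_coding(self):
        df = pd.DataFrame({"panel": ["a"] * 5 + ["b"] * 5, "x": np.arange(10.0)})
        y = np.r_[np.zeros(5), np.ones(5)] * 3 + 0.1 * df["x"].values
        out = ols_regress(y, df)
        assert out["table"].loc["panel[b]", "coef"] == pytest.approx(3.0, abs=0.3)

    def test_rank_deficiency_names_column(self):
        df = pd.DataFrame({"x": np.arange(8.0), "x2": 2 * np.arange(8.0)})
        with pytest.raises(ValueError, match="x"):
            ols_regress(np.arange(8.0), df)

    def test_row_permutation_invariance(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "z": rng.normal(size=30)})
        y = df["x"].values + rng.normal(size=30)
        a = ols_regress(y, df)["table"]["coef"]
        perm = rng.permutation(30)
        b = ols_regress(y[perm], df.iloc[perm].reset_index(drop=True))["table"]["coef"]
        assert np.allclose(a.values, b.values)

    def test_null_slope_p_uniformish(self, rng):
        ps = []
        for _ in range(200):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            ps.append(ols_regress(y, pd.DataFrame({"x": x}))["table"].loc["x", "p"])
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.12


class TestCorrelationSuite:
    def test_self_correlation_is_one(self, rng):
        v = rng.normal(size=50)
        summary, pairs = correlation_suite({1.0: v, 2.0: v.copy()}, 1.0)
        assert np.allclose(summary["r"], 1.0)

    def test_anticorrelated_pair(self, rng):
        v = rng.normal(size=50)
        summary, _ = correlation_suite({1.0: v, 2.0: -v}, 1.0)
        assert summary.set_index("depth").loc[2.0, "r"] == pytest.approx(-1.0)

    def test_too_few_pairs_flagged(self):
        v = np.array([1.0, np.nan, np.nan, np.nan])
        w = np.array([1.0, 2.0, np.nan, np.nan])
        summary, _ = correlation_suite({1.0: v, 2.0: w}, 1.0)
        assert np.isnan(summary.set_index("depth").loc[2.0, "r"])


class TestWindowMetrics:
    def test_reference_callset_has_zero_discordance(self, small_panel, small_cohort):
        from haplopass.impute import impute_phase
        from haplopass.likelihoods import naive_calls, pileup_to_gl

        pu = simulate_pileup(small_cohort, 17.4, seed=21)
        gl = pileup_to_gl(pu)
        cs = impute_phase(gl, small_panel)
        calls = cs.genotypes
        z = np.zeros(small_panel.n_sites)
        table = window_metrics(
            {17.4: cs}, calls, {17.4: pu}, {17.4: z}, small_panel.positions,
            ref_post=cs, window_bp=1e6, trim_quantiles=(0.0, 1.0),
        )
        assert np.allclose(table["geno_discordance"], 0.0)
        assert np.allclose(table["hapA_discordance"], 0.0)

    def test_quantile_trim_keeps_interior_windows(self, small_panel, small_cohort):
        from haplopass.impute import impute_phase
        from haplopass.likelihoods import pileup_to_gl

        pu = simulate_pileup(small_cohort, 9.6, seed=22)
        cs = impute_phase(pileup_to_gl(pu), small_panel)
        z = np.zeros(small_panel.n_sites)
        full = window_metrics({9.6: cs}, cs.genotypes, {9.6: pu}, {9.6: z},
                              small_panel.positions, window_bp=2e5,
                              trim_quantiles=(0.0, 1.0))
        trimmed = window_metrics({9.6: cs}, cs.genotypes, {9.6: pu}, {9.6: z},
                                 small_panel.positions, window_bp=2e5,
                                 trim_quantiles=(0.1, 0.9))
        assert 0 < len(trimmed) < len(full)
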