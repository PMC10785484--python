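"""Diploid copying-model imputation: posteriors, phasing, INFO, masking."""

import numpy as np
import pytest

from haplopass.impute import (
    LSParams,
    LiStephensImputer,
    impute_phase,
    info_score,
    ls_posteriors,
    mask_low_gp,
)
from haplopass.likelihoods import pileup_to_gl
from haplopass.simulate import (
    HaplotypePanel,
    simulate_cohort,
    simulate_panel,
    simulate_pileup,
)

from _oracles import ls_enumerate, ls_best_path_prob, ls_max_path


def _tiny_panel(alleles, positions=None):
    alleles = np.asarray(alleles, np.int8)
    K, M = alleles.shape
    pos = np.arange(1, M + 1) * 1000 if positions is None else np.asarray(positions)
    return HaplotypePanel(
        alleles=alleles,
        positions=np.asarray(pos, np.int64),
        panel_af=alleles.mean(axis=0),
        breed_label=np.array(["b0"] * K, dtype=object),
    )


def _rand_gl(rng, M):
    gl = rng.random((M, 3))
    return gl / gl.sum(axis=1, keepdims=True)


class TestForwardBackwardOracle:
    @pytest.mark.parametrize("K,M,seed", [(2, 2, 0), (3, 3, 1), (4, 3, 2), (2, 4, 3), (4, 4, 4)])
    def test_posteriors_match_exhaustive_enumeration(self, K, M, seed):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(0, 2, (K, M)).astype(np.int8)
        panel = _tiny_panel(alleles)
        gl = _rand_gl(rng, M)
        params = LSParams(recomb_rate=1.0, ne_scale=2e-4, mismatch_theta=0.07)
        gp, ll, post = ls_posteriors(gl, panel, params, return_state_posteriors=True)
        rho = params.rho(panel.positions)
        marg, gmarg, ll_o = ls_enumerate(gl, alleles, rho, 0.07)
        assert np.abs(post - marg).max() < 1e-10
        assert np.abs(gp - gmarg).max() < 1e-10
        assert abs(ll - ll_o) < 1e-9

    def test_genotype_posteriors_sum_to_one(self, rng):
        alleles = rng.integers(0, 2, (6, 40)).astype(np.int8)
        panel = _tiny_panel(alleles)
        gp, _ = ls_posteriors(_rand_gl(rng, 40), panel)
        assert np.allclose(gp.sum(axis=1), 1.0, atol=1e-9)

    def test_degenerate_identical_panel_concentrates_on_panel_homozygote(self):
        # two identical haplotypes, flat GL: the copying prior dominates
        alleles = np.array([[1, 0, 1], [1, 0, 1]], np.int8)
        panel = _tiny_panel(alleles)
        gl = np.full((3, 3), 1 / 3)
        theta = 0.02
        gp, _ = ls_posteriors(gl, panel, LSParams(mismatch_theta=theta))
        expected = [2, 0, 2]
        for m, g in enumerate(expected):
            assert gp[m].argmax() == g
            assert gp[m, g] > (1 - theta) ** 2 - 0.01

    def test_truth_in_panel_high_depth_posteriors_confident(self, small_panel):
        truth = simulate_cohort(small_panel, 5, 1, private_allele_rate=0.0,
                                mosaic_switch_rate=0.0, seed=3)
        gl = pileup_to_gl(simulate_pileup(truth, 43.5, seed=4))
        frac_confident = []
        for i in range(5):
            gp, _ = ls_posteriors(gl.gl[i], small_panel)
            frac_confident.append((gp.max(axis=1) > 0.99).mean())
        assert np.mean(frac_confident) > 0.99

    def test_panel_cap_rejected(self, rng):
        alleles = rng.integers(0, 2, (514, 3)).astype(np.int8)
        with pytest.raises(ValueError, match="chunk"):
            ls_posteriors(_rand_gl(rng, 3), _tiny_panel(alleles))


class TestViterbi:
    def test_matches_brute_force_max_path(self):
        from haplopass import _hmm

        for seed in range(10):
            rng = np.random.default_rng(seed)
            K, M = 3, 3
            alleles = rng.integers(0, 2, (K, M)).astype(np.int8)
            gl = _rand_gl(rng, M)[None]
            rho = rng.random(M - 1) * 0.3
            path = _hmm.viterbi(gl, alleles, rho, 0.08)[0]
            p_mine = ls_best_path_prob(gl[0], alleles, rho, 0.08, path)
            _, p_best = ls_max_path(gl[0], alleles, rho, 0.08)
            assert abs(p_mine - p_best) <= 1e-12 * p_best

    def test_deterministic_across_runs(self, small_panel, small_cohort):
        gl = pileup_to_gl(simulate_pileup(small_cohort, 3.8, seed=5))
        a = impute_phase(gl, small_panel)
        b = impute_phase(gl, small_panel)
        assert np.array_equal(a.phased, b.phased)
        assert np.array_equal(a.gp, b.gp)


class TestImputePhase:
    def test_single_chunk_equals_multichunk_when_chunk_covers_span(
        self, small_panel, small_cohort
    ):
        gl = pileup_to_gl(simulate_pileup(small_cohort, 9.6, seed=6))
        one = impute_phase(gl, small_panel, chunk_bp=1e9)
        many = impute_phase(gl, small_panel, chunk_bp=4e9)
        assert np.array_equal(one.phased, many.phased)

    def test_chunked_run_ligates_consistently(self, small_panel, small_cohort):
        gl = pileup_to_gl(simulate_pileup(small_cohort, 17.4, seed=7))
        whole = impute_phase(gl, small_panel)
        chunked = impute_phase(gl, small_panel, chunk_bp=1_000_000, chunk_overlap_bp=200_000)
        agree = (whole.genotypes == chunked.genotypes).mean()
        assert agree > 0.99
        # haplotype labelling must not flip mid-chromosome: per individual the
        # chunked phases agree with the whole-run phases in one orientation
        for i in range(small_cohort.n_individuals):
            same = (chunked.phased[i] == whole.phased[i]).all(axis=1).mean()
            swap = (chunked.phased[i] == whole.phased[i][:, ::-1]).all(axis=1).mean()
            assert max(same, swap) > 0.95

    def test_phased_haplotypes_recover_truth_at_high_depth(self, small_panel):
        truth = simulate_cohort(small_panel, 10, 2, private_allele_rate=0.0,
                                mosaic_switch_rate=1e-7, seed=8)
        gl = pileup_to_gl(simulate_pileup(truth, 17.4, seed=9))
        cs = impute_phase(gl, small_panel)
        accs = []
        for i in range(10):
            a1 = ((cs.phased[i, :, 0] == truth.hapA[i]) & (cs.phased[i, :, 1] == truth.hapB[i])).mean()
            a2 = ((cs.phased[i, :, 0] == truth.hapB[i]) & (cs.phased[i, :, 1] == truth.hapA[i])).mean()
            accs.append(max(a1, a2))
        assert np.mean(accs) > 0.995

    def test_private_alleles_pull_dosage_toward_panel(self, small_panel):
        truth = simulate_cohort(small_panel, 10, 2, private_allele_rate=0.01,
                                mosaic_switch_rate=1e-7, seed=10)
        gl = pileup_to_gl(simulate_pileup(truth, 3.8, seed=11))
        cs = impute_phase(gl, small_panel)
        err = np.abs(cs.dosage - truth.genotypes)
        private_cells = truth.private_mask.any(axis=1)
        assert private_cells.sum() > 10
        assert err[private_cells].mean() > err[~private_cells].mean()

    def test_phase_sampling_is_seeded_and_differs_between_seeds(
        self, small_panel, small_cohort
    ):
        gl = pileup_to_gl(simulate_pileup(small_cohort, 0.9, seed=12))
        a = impute_phase(gl, small_panel, phase_method="sample", phase_seed=1)
        a2 = impute_phase(gl, small_panel, phase_method="sample", phase_seed=1)
        b = impute_phase(gl, small_panel, phase_method="sample", phase_seed=2)
        assert np.array_equal(a.phased, a2.phased)
        assert not np.array_equal(a.phased, b.phased)
        # genotype posteriors are unaffected by the phasing rule
        assert np.allclose(a.gp, b.gp)

    def test_site_list_mismatch_rejected(self, small_panel, small_cohort):
        gl = pileup_to_gl(simulate_pileup(small_cohort, 3.8, seed=13))
        gl.gl = gl.gl[:, :-1]
        with pytest.raises(ValueError, match="site list"):
            impute_phase(gl, small_panel)


class TestInfoScore:
    def test_degenerate_triplets_give_one(self):
        gp = np.tile([0.0, 1.0, 0.0], (4, 1))
        assert info_score(gp) == 1.0

    def test_hand_computed_zero(self):
        # two individuals at (0.25, 0.5, 0.25): theta = 0.5, info = 0
        gp = np.tile([0.25, 0.5, 0.25], (2, 1))
        assert info_score(gp) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_individual_order(self, rng):
        gp = rng.dirichlet([1, 1, 1], size=20)
        assert info_score(gp) == pytest.approx(info_score(gp[::-1]))

    def test_monomorphic_convention(self):
        gp = np.tile([1.0, 0.0, 0.0], (3, 1))
        assert info_score(gp) == 1.0


class TestMaskLowGp:
    def test_threshold_masks_uncertain_cells(self, small_panel, small_cohort):
        gl = pileup_to_gl(simulate_pileup(small_cohort, 0.9, seed=14))
        cs = impute_phase(gl, small_panel)
        masked = mask_low_gp(cs, 0.95)
        uncertain = cs.gp.max(axis=-1) < 0.95
        assert np.array_equal(masked.missing, uncertain)
        # a specific uncertain triplet is masked
        assert uncertain[masked.missing].all()

    def test_masking_rate_decreases_with_depth(self, small_panel, small_cohort):
        rates = {}
        for d, seed in [(0.9, 15), (17.4, 16)]:
            gl = pileup_to_gl(simulate_pileup(small_cohort, d, seed=seed))
            cs = mask_low_gp(impute_phase(gl, small_panel), 0.95)
            rates[d] = cs.missing.mean()
        assert rates[0.9] > rates[17.4]

    def test_bad_threshold_rejected(self, small_panel, small_cohort):
        gl = pileup_to_gl(simulate_pileup(small_cohort, 3.8, seed=17))
        cs = impute_phase(gl, small_panel)
        with pytest.raises(ValueError):
            mask_low_gp(cs, 0.0)


class TestEstimatorSurface:
    def test_fit_transform_and_get_params(self, small_panel, small_cohort):
        gl = pileup_to_gl(simulate_pileup(small_cohort, 9.6, seed=18))
        imp = LiStephensImputer(gp_threshold=0.95)
        assert "gp_threshold" in imp.get_params()
        cs = imp.fit(small_panel).transform(gl)
        assert cs.phased.shape == (small_cohort.n_individuals, small_panel.n_sites, 2)
        assert np.allclose(cs.gp.sum(-1), 1.0, atol=1e-9)
        assert np.allclose(cs.dosage, cs.gp[..., 1] + 2 * cs.gp[..., 2])
        # phased alleles sum to the argmax-GP genotype everywhere
        assert np.array_equal(cs.phased.sum(-1), cs.gp.argmax(-1))

    def test_transform_before_fit_raises(self, small_panel, small_cohort):
        gl = pileup_to_gl(simulate_pileup(small_cohort, 9.6, seed=19))
        with pytest.raises(RuntimeError):
            LiStephensImputer().transform(gl)
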