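import numpy as np
import pytest
from scipy import stats

from pgspart import synthetic_data as sd


class TestSpecValidation:
    @pytest.mark.parametrize("bad", [
        {"M": 100, "L": 7},            # not divisible
        {"maf_range": (0.0, 0.3)},
        {"maf_range": (0.2, 0.6)},
        {"h2_target": 1.2},
        {"pi_causal_anchor": -0.1},
        {"rho_block": 1.0},
    ])
    def test_invalid_architecture_rejected(self, bad):
        with pytest.raises(ValueError):
            sd.ArchitectureSpec(**bad)

    def test_category_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sd.CohortSpec(category_base_probs=(0.3, 0.3, 0.3, 0.3))


class TestGenotypes:
    def test_same_seed_bit_identical(self, tiny_arch):
        a = sd.simulate_genotypes(tiny_arch, n=50, seed=3)
        b = sd.simulate_genotypes(tiny_arch, n=50, seed=3)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_dosages_are_biallelic_counts(self, tiny_genotypes):
        d = tiny_genotypes.dosages
        assert d.min() >= 0.0 and d.max() <= 2.0
        assert set(np.unique(d)) <= {0.0, 1.0, 2.0}

    def test_independent_blocks_when_rho_zero(self):
        spec = sd.ArchitectureSpec(M=200, L=10, rho_block=0.0,
                                   rho_block_range=None, seed=5)
        g = sd.simulate_genotypes(spec, n=2000)
        c = np.corrcoef(g.dosages.T)
        # mean |correlation| across different blocks
        block = np.repeat(np.arange(10), 20)
        off = np.abs(c[block[:, None] != block[None, :]])
        assert off.mean() < 0.1

    def test_within_block_correlation_matches_spec(self):
        spec = sd.ArchitectureSpec(M=100, L=5, rho_block=0.4,
                                   rho_block_range=None, seed=5)
        g = sd.simulate_genotypes(spec, n=4000)
        block = np.repeat(np.arange(5), 20)
        c = np.corrcoef(g.dosages.T)
        within = c[(block[:, None] == block[None, :])
                   & ~np.eye(100, dtype=bool)]
        assert abs(within.mean() - 0.4) < 0.03

    def test_fixed_maf_realized_within_binomial_error(self):
        spec = sd.ArchitectureSpec(M=200, L=10, maf_range=(0.3, 0.3), seed=9)
        n = 3000
        g = sd.simulate_genotypes(spec, n=n)
        freq = g.dosages.mean(axis=0) / 2.0
        se = np.sqrt(0.3 * 0.7 / (2 * n))
        # the copula correlates SNPs within a block, widening the frequency
        # spread relative to independent sampling; bound via effective n
        assert np.all(np.abs(freq - 0.3) < 6 * se)


class TestTrueEffects:
    def test_sign_concordance_forced_at_q1(self):
        spec = sd.ArchitectureSpec(M=2000, L=100, q_concordant=1.0,
                                   pi_causal_anchor=0.8,
                                   pi_causal_target=0.8, seed=3)
        eff = sd.draw_true_effects(spec)
        sh = eff.shared_causal
        assert sh.sum() > 500
        assert np.all(np.sign(eff.beta_target[sh])
                      == np.sign(eff.beta_anchor[sh]))

    def test_concordance_fraction_tracks_q(self):
        spec = sd.ArchitectureSpec(M=4000, L=200, q_concordant=0.3,
                                   pi_causal_anchor=0.7,
                                   pi_causal_target=0.7, seed=3)
        eff = sd.draw_true_effects(spec)
        sh = eff.shared_causal
        assert sh.sum() >= 1000
        frac = np.mean(np.sign(eff.beta_target[sh])
                       == np.sign(eff.beta_anchor[sh]))
        assert abs(frac - 0.3) < 0.03

    def test_population_h2_is_exact_under_block_ld(self, tiny_arch,
                                                   tiny_effects):
        q = sd._blockwise_quadratic(tiny_effects.beta_target,
                                    tiny_arch.block_rhos(), tiny_arch.L)
        assert q == pytest.approx(tiny_arch.h2_target, abs=1e-12)

    def test_realized_genetic_variance_matches_h2(self):
        # empirical check of the variance bookkeeping on a sampled panel
        spec = sd.ArchitectureSpec(M=5000, L=250, seed=21)
        eff = sd.draw_true_effects(spec)
        g = sd.simulate_genotypes(spec, n=5000, seed=22)
        gv = g.standardized() @ eff.beta_target
        assert abs(gv.var(ddof=1) - spec.h2_target) < 0.03


class TestSumstats:
    def test_null_trait_has_uniform_pvalues(self):
        spec = sd.ArchitectureSpec(M=10000, L=500, pi_causal_anchor=0.0,
                                   pi_causal_target=0.0, seed=17)
        eff = sd.draw_true_effects(spec)
        _, target = sd.simulate_sumstats(spec, eff, seed=18)
        frac = (target["P"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.01

    def test_noise_free_estimates_equal_truth(self, tiny_arch, tiny_effects):
        _, target = sd.simulate_sumstats(tiny_arch, tiny_effects,
                                         noise=False)
        scale = np.sqrt(2 * target["FRQ"] * (1 - target["FRQ"]))
        np.testing.assert_allclose(target["BETA"] * scale,
                                   tiny_effects.beta_target, atol=1e-12)

    def test_seeded_determinism(self, tiny_arch, tiny_effects):
        a1, t1 = sd.simulate_sumstats(tiny_arch, tiny_effects, seed=4)
        a2, t2 = sd.simulate_sumstats(tiny_arch, tiny_effects, seed=4)
        np.testing.assert_array_equal(t1["BETA"], t2["BETA"])
        np.testing.assert_array_equal(a1["P"], a2["P"])


class TestSecondTarget:
    def test_shares_anchor_and_controls_own_concordance(self, tiny_arch,
                                                        tiny_effects):
        spec = sd.ArchitectureSpec(M=4000, L=200, pi_causal_anchor=0.7,
                                   pi_causal_target=0.7, seed=3)
        eff1 = sd.draw_true_effects(spec)
        eff2 = sd.draw_second_target(spec, eff1, q_concordant=0.9, seed=31)
        np.testing.assert_array_equal(eff1.beta_anchor, eff2.beta_anchor)
        sh = eff2.shared_causal
        frac = np.mean(np.sign(eff2.beta_target[sh])
                       == np.sign(eff2.beta_anchor[sh]))
        assert abs(frac - 0.9) < 0.03


class TestCohort:
    def test_null_loadings_recover_base_probs(self):
        spec = sd.ArchitectureSpec(M=400, L=20, seed=7)
        eff = sd.draw_true_effects(spec)
        g = sd.simulate_genotypes(spec, n=5000, seed=41)
        cs = sd.CohortSpec(
            n_individuals=5000, gamma_concordant=0.0, gamma_discordant=0.0,
            a_med=0.0, b_med=0.0, beta_age=0.0, beta_sex=0.0, beta_ses=0.0,
            school_sd=0.0, seed=41)
        cohort, _ = sd.simulate_cohort(cs, g, eff)
        counts = (cohort.phenotypes["grade_mathematics"]
                  .value_counts(normalize=True).sort_index())
        for k, p in enumerate(cs.category_base_probs):
            se = np.sqrt(p * (1 - p) / 5000)
            assert abs(counts[k] - p) < 4 * se

    def test_null_mediator_path_uncorrelated_with_score(self, tiny_arch,
                                                        tiny_effects):
        g = sd.simulate_genotypes(tiny_arch, n=4000, seed=43)
        cs = sd.CohortSpec(n_individuals=4000, a_med=0.0, seed=43)
        cohort, truth = sd.simulate_cohort(cs, g, tiny_effects)
        s = truth.s_concordant + truth.s_discordant
        r = np.corrcoef(truth.mediator_latent, s)[0, 1]
        assert abs(r) < 0.05

    def test_zero_school_sd_gives_zero_school_effects(self, tiny_arch,
                                                      tiny_effects,
                                                      tiny_genotypes):
        cs = sd.CohortSpec(n_individuals=600, school_sd=0.0, seed=3)
        _, truth = sd.simulate_cohort(cs, tiny_genotypes, tiny_effects)
        assert np.all(truth.school_effects == 0.0)

    def test_mediator_scale_nonnegative(self, tiny_arch, tiny_effects,
                                        tiny_genotypes):
        cs = sd.CohortSpec(n_individuals=600, seed=3)
        cohort, _ = sd.simulate_cohort(cs, tiny_genotypes, tiny_effects)
        assert (cohort.phenotypes["symptoms"] >= 0).all()

    def test_dimension_mismatch_raises(self, tiny_effects, tiny_genotypes):
        cs = sd.CohortSpec(n_individuals=999, seed=3)
        with pytest.raises(ValueError):
            sd.simulate_cohort(cs, tiny_genotypes, tiny_effects)


class TestLdZscores:
    def test_mean_matches_ld_convolution(self):
        spec = sd.ArchitectureSpec(M=2000, L=100, rho_block=0.5,
                                   rho_block_range=None, seed=5)
        eff = sd.draw_true_effects(spec)
        reps = [sd.simulate_ld_zscores(spec, eff.beta_target, N=10000,
                                       seed=s) for s in range(40)]
        zbar = np.mean(reps, axis=0)
        b = eff.beta_target.reshape(spec.L, -1)
        expected = np.sqrt(10000) * (
            (1 - 0.5) * b + 0.5 * b.sum(axis=1, keepdims=True)).ravel()
        resid = zbar - expected
        assert np.abs(resid).mean() < 3.0 / np.sqrt(40)
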