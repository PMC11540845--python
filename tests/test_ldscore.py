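import numpy as np
import pandas as pd
import pytest

from pgspart import synthetic_data as sd
from pgspart.exceptions import ConfigError, InputDataError
from pgspart.ldscore import (block_model_ld_scores, compute_ld_scores,
                             cts_style_enrichment, gws_enrichment,
                             stratified_covariance, stratified_h2)


def block_annotations(m, masks):
    return pd.DataFrame({name: mask.astype(float)
                         for name, mask in masks.items()})


class TestComputeLdScores:
    def test_isolated_snp_scores_one(self, rng):
        dos = rng.binomial(2, 0.3, size=(500, 5)).astype(float)
        ld = compute_ld_scores(dos, window=4)
        # independent SNPs: adjusted off-diagonal r2 ~ 0, self term = 1
        np.testing.assert_allclose(ld.scores["total"], 1.0, atol=0.15)

    def test_block_model_expectation(self):
        spec = sd.ArchitectureSpec(M=100, L=10, rho_block=0.5,
                                   rho_block_range=None, seed=3)
        g = sd.simulate_genotypes(spec, n=1500, seed=4)
        ld = compute_ld_scores(g.dosages, window=spec.block_size)
        expected = 1.0 + (spec.block_size - 1) * 0.5 ** 2
        assert ld.scores["total"].mean() == pytest.approx(expected, rel=0.06)

    def test_partitioned_scores_sum_to_total(self, rng):
        dos = rng.binomial(2, 0.4, size=(300, 30)).astype(float)
        masks = {"a": np.arange(30) < 10,
                 "b": (np.arange(30) >= 10) & (np.arange(30) < 20),
                 "c": np.arange(30) >= 20}
        ld = compute_ld_scores(dos, block_annotations(30, masks), window=29)
        total = ld.scores[["a", "b", "c"]].sum(axis=1)
        np.testing.assert_allclose(total, ld.scores["total"], atol=1e-10)

    def test_analytic_block_scores(self):
        ld = block_model_ld_scores(L=4, B=5, rho=0.6,
                                   annotations=None)
        np.testing.assert_allclose(ld.scores["total"],
                                   1.0 + 4 * 0.36, atol=1e-12)

    def test_tiny_panel_rejected(self):
        with pytest.raises(InputDataError):
            compute_ld_scores(np.zeros((2, 5)))


def simulate_h2_zscores(spec, mask, h2, N, seed, rng=None):
    """z-scores for a trait whose heritability sits entirely in ``mask``."""
    local = np.random.default_rng(seed) if rng is None else rng
    beta = np.zeros(spec.M)
    beta[mask] = local.standard_normal(mask.sum())
    q = sd._blockwise_quadratic(beta, spec.block_rhos(), spec.L)
    if q > 0:
        beta *= np.sqrt(h2 / q)
    z = sd.simulate_ld_zscores(spec, beta, N=N, rng=local)
    return z, beta


class TestStratifiedH2:
    spec = sd.ArchitectureSpec(M=6000, L=300, seed=5)
    mask_a = np.arange(6000) % 3 == 0  # one third of SNPs
    ann = block_annotations(6000, {"A": mask_a, "B": ~mask_a})
    ld = block_model_ld_scores(300, 20, spec.block_rhos(), ann)

    def test_null_trait_within_two_se_of_zero(self):
        rng = np.random.default_rng(6)
        z = sd.simulate_ld_zscores(self.spec, np.zeros(6000), N=50000,
                                   rng=rng)
        res = stratified_h2(z, 50000, self.ld)
        assert abs(res.total) < 2.5 * res.total_se
        assert abs(res.intercept - 1.0) < 2.5 * res.intercept_se

    def test_concentrated_h2_recovered_per_partition(self):
        rng = np.random.default_rng(7)
        est_a, est_b = [], []
        for _ in range(20):
            z, _ = simulate_h2_zscores(self.spec, self.mask_a, 0.2,
                                       50000, seed=None, rng=rng)
            res = stratified_h2(z, 50000, self.ld)
            by = res.by_annotation()
            est_a.append(by["A"])
            est_b.append(by["B"])
        assert abs(np.mean(est_a) - 0.2) < 0.03
        assert abs(np.mean(est_b)) < 0.03

    def test_uniform_signal_gives_unit_enrichment(self):
        rng = np.random.default_rng(8)
        ests = []
        for _ in range(10):
            z, _ = simulate_h2_zscores(self.spec,
                                       np.ones(6000, dtype=bool), 0.3,
                                       50000, seed=None, rng=rng)
            res = stratified_h2(z, 50000, self.ld)
            row = res.coefficients.set_index("annotation")
            ests.append(row.loc["A", "enrichment"])
        assert np.mean(ests) == pytest.approx(1.0, abs=0.25)

    def test_collinear_annotations_rejected(self):
        ann = block_annotations(6000, {"A": self.mask_a, "A2": self.mask_a})
        ld = block_model_ld_scores(300, 20, self.spec.block_rhos(), ann)
        rng = np.random.default_rng(9)
        z = sd.simulate_ld_zscores(self.spec, np.zeros(6000), N=1000,
                                   rng=rng)
        with pytest.raises(ConfigError):
            stratified_h2(z, 1000, ld)


class TestGwsEnrichment:
    def test_proportional_hits_are_null(self):
        labels = np.array(["a"] * 100 + ["b"] * 900)
        p = np.ones(1000)
        p[:10] = 1e-9     # 10% of hits in 10% partition
        p[100:190] = 1e-9
        out = gws_enrichment(p, labels)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        # 100 hits; partition holding 10% of SNPs gets 30 of them
        labels = np.array(["small"] * 100 + ["big"] * 900)
        p = np.ones(1000)
        p[:30] = 1e-9
        p[100:170] = 1e-9
        out = gws_enrichment(p, labels)
        assert out["chi2"] == pytest.approx((30 - 10) ** 2 / 10
                                            + (70 - 90) ** 2 / 90, abs=1e-9)
        assert out["chi2"] == pytest.approx(44.44, abs=0.01)

    def test_no_hits_rejected(self):
        with pytest.raises(InputDataError):
            gws_enrichment(np.full(100, 0.5), np.array(["a"] * 100))


class TestStratifiedCovariance:
    spec = sd.ArchitectureSpec(M=6000, L=300, seed=5)
    ann = block_annotations(6000, {"all": np.ones(6000, dtype=bool)})
    ld = block_model_ld_scores(300, 20, spec.block_rhos(), ann)

    def test_identical_traits_recover_h2(self):
        rng = np.random.default_rng(10)
        ests = []
        for _ in range(15):
            beta = np.zeros(6000)
            beta[rng.random(6000) < 0.3] = 1.0
            beta[beta > 0] = rng.standard_normal(int((beta > 0).sum()))
            q = sd._blockwise_quadratic(beta, self.spec.block_rhos(), 300)
            beta *= np.sqrt(0.2 / q)
            z1 = sd.simulate_ld_zscores(self.spec, beta, N=50000, rng=rng)
            z2 = sd.simulate_ld_zscores(self.spec, beta, N=50000, rng=rng)
            res = stratified_covariance(z1, z2, 50000, 50000, self.ld)
            ests.append(res.total)
        assert abs(np.mean(ests) - 0.2) < 0.04

    def test_independent_traits_within_two_se_of_zero(self):
        rng = np.random.default_rng(11)
        z1, _ = simulate_h2_zscores(self.spec, np.arange(6000) % 2 == 0,
                                    0.2, 50000, seed=None, rng=rng)
        z2, _ = simulate_h2_zscores(self.spec, np.arange(6000) % 2 == 0,
                                    0.2, 50000, seed=None, rng=rng)
        res = stratified_covariance(z1, z2, 50000, 50000, self.ld)
        assert abs(res.total) < 2.5 * res.total_se

    def test_symmetric_in_traits(self):
        rng = np.random.default_rng(12)
        z1 = rng.standard_normal(6000)
        z2 = rng.standard_normal(6000)
        a = stratified_covariance(z1, z2, 30000, 40000, self.ld)
        b = stratified_covariance(z2, z1, 40000, 30000, self.ld)
        assert a.total == pytest.approx(b.total, abs=1e-12)

    def test_too_few_variants_refused(self):
        ann = block_annotations(100, {"all": np.ones(100, dtype=bool)})
        ld = block_model_ld_scores(10, 10, 0.5, ann)
        with pytest.raises(InputDataError):
            stratified_covariance(np.zeros(100), np.zeros(100), 1000, 1000,
                                  ld)


class TestCtsEnrichment:
    spec = sd.ArchitectureSpec(M=6000, L=300, seed=5)

    def _ld_computer(self, ann):
        return block_model_ld_scores(300, 20, self.spec.block_rhos(), ann)

    def test_secondary_all_snps_reduces_to_partition(self):
        rng = np.random.default_rng(13)
        part = np.arange(6000) % 4 == 0
        z, _ = simulate_h2_zscores(self.spec, part, 0.3, 50000,
                                   seed=None, rng=rng)
        out = cts_style_enrichment(z, 50000, part,
                                   np.ones(6000, dtype=bool),
                                   self._ld_computer, mode="anti-target")
        # target = partition, anti-target reference = complement
        assert out["m_target"] == int(part.sum())
        assert out["m_reference"] == int((~part).sum())
        assert out["p_one_sided"] < 0.05

    def test_signal_confined_to_intersection_detected(self):
        rng = np.random.default_rng(14)
        part = np.arange(6000) % 2 == 0
        cell = np.arange(6000) % 3 == 0
        target = part & cell
        hits = 0
        for _ in range(5):
            z, _ = simulate_h2_zscores(self.spec, target, 0.3, 50000,
                                       seed=None, rng=rng)
            out = cts_style_enrichment(z, 50000, part, cell,
                                       self._ld_computer,
                                       mode="anti-target")
            hits += out["p_one_sided"] < 0.05
        assert hits >= 4

    def test_uniform_signal_null_in_control_mode(self):
        rng = np.random.default_rng(15)
        part = np.arange(6000) % 2 == 0
        cell = np.arange(6000) % 3 == 0
        sig = 0
        for _ in range(10):
            z, _ = simulate_h2_zscores(self.spec, part, 0.3, 50000,
                                       seed=None, rng=rng)
            out = cts_style_enrichment(z, 50000, part, cell,
                                       self._ld_computer, mode="control")
            sig += out["p_one_sided"] < 0.05
        assert sig <= 2

    def test_empty_intersection_skipped(self):
        part = np.arange(6000) < 3000
        cell = np.arange(6000) >= 3000
        out = cts_style_enrichment(np.zeros(6000), 1000, part, cell,
                                   self._ld_computer)
        assert out.get("skipped")
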