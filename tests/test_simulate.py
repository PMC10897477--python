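import numpy as np
import pytest
from scipy import stats

import triofactor as tf
from triofactor.simulate import draw_unique_components

from conftest import single_factor_config


def _couple_corr(couples, k):
    return np.array([
        np.corrcoef(couples[:, j], couples[:, k + j])[0, 1] for j in range(k)
    ])


class TestCouples:
    def test_independence_case(self):
        cfg = tf.default_config(n_trios=200_000, seed=1)
        couples = tf.simulate_couples(cfg)
        assert np.abs(_couple_corr(couples, 4)).max() < 0.01

    def test_assortment_recovered(self):
        g = np.zeros(4)
        g[3] = 0.257
        cfg = tf.default_config(n_trios=200_000, seed=2,
                                partner_cross_cov=np.diag(g))
        corr = _couple_corr(tf.simulate_couples(cfg), 4)
        mc_se = 1.0 / np.sqrt(cfg.n_trios)
        assert abs(corr[3] - 0.257) < 3 * mc_se
        assert np.abs(corr[:3]).max() < 3 * mc_se

    def test_seed_reproducibility(self):
        cfg = tf.default_config(n_trios=500, seed=11)
        a = tf.simulate_couples(cfg)
        b = tf.simulate_couples(tf.default_config(n_trios=500, seed=11))
        np.testing.assert_array_equal(a, b)

    def test_non_psd_joint_names_block(self):
        cfg = tf.default_config(n_trios=10)
        cfg.partner_cross_cov = np.diag([1.2, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="Gamma"):
            tf.simulate_couples(cfg)

    def test_selection_mean_shift(self):
        am = np.array([0.0, 0.3, 0.0, 0.0])
        cfg = tf.default_config(n_trios=200_000, seed=3,
                                selection_means_mother=am)
        couples = tf.simulate_couples(cfg)
        se = 1.0 / np.sqrt(cfg.n_trios)
        assert abs(couples[:, 1].mean() - 0.3) < 3 * se
        assert abs(couples[:, 4 + 1].mean()) < 3 * se  # father unshifted

    def test_threshold_mode_shifts_means_upward(self):
        cfg = tf.default_config(
            n_trios=30_000, seed=4, selection_mode="threshold",
            selection_means_father=np.array([0.0, 0.0, 0.0, 0.5]),
        )
        couples = tf.simulate_couples(cfg)
        assert couples.shape == (30_000, 8)
        assert couples[:, 4 + 3].mean() > 0.1  # fathers selected on CONS
        assert abs(couples[:, 3].mean()) < 0.05  # mothers barely affected


class TestTransmission:
    def test_child_variance_bookkeeping(self):
        cfg = tf.default_config(n_trios=200_000, seed=5)
        rng = np.random.default_rng(5)
        couples = tf.simulate_couples(cfg, rng)
        fc, _ = tf.transmit(couples[:, :4], None, couples[:, 4:], None, cfg, rng)
        # 0.25 + 0.25 + 0.5 = 1 forced by the fixed 0.5 paths
        assert np.allclose(fc.var(axis=0), 1.0, atol=3.0 / np.sqrt(cfg.n_trios))

    def test_within_family_covariance_matches_half_population(self, big_dataset):
        cfg, ds = big_dataset
        dev = ds.within_deviations()
        emp = np.cov(dev, rowvar=False)
        target = 0.5 * cfg.population_cov()
        mc_se = 3.0 / np.sqrt(cfg.n_trios)
        assert np.abs(emp - target).max() < 3 * mc_se

    def test_no_segregation_limit_is_exact_midparent(self):
        cfg = tf.default_config(n_trios=100, seed=6)
        rng = np.random.default_rng(0)
        couples = tf.simulate_couples(cfg, rng)
        um, uf = draw_unique_components(cfg, rng)
        fc, uc = tf.transmit(couples[:, :4], um, couples[:, 4:], uf, cfg, rng,
                             segregation_scale=0.0)
        np.testing.assert_allclose(fc, 0.5 * (couples[:, :4] + couples[:, 4:]))
        np.testing.assert_allclose(uc, 0.5 * (um + uf))

    def test_dimension_mismatch_rejected(self):
        cfg = tf.default_config(n_trios=10)
        with pytest.raises(ValueError, match="shape"):
            tf.transmit(np.zeros((10, 4)), None, np.zeros((9, 4)), None, cfg)


class TestEmit:
    def test_zero_loadings_passthrough(self):
        cfg = single_factor_config(n_trios=50, loadings=np.zeros((6, 1)),
                                   unique_var=np.ones(6))
        ds = tf.simulate_trios(cfg)
        np.testing.assert_allclose(
            ds.scores["mother"], ds.latent_truth["mother"]["uniques"])

    def test_identity_mapping_single_factor(self):
        lam = np.zeros((6, 1))
        lam[0, 0] = 1.0
        cfg = single_factor_config(n_trios=50, loadings=lam,
                                   unique_var=np.zeros(6))
        ds = tf.simulate_trios(cfg)
        np.testing.assert_allclose(
            ds.scores["child"][:, 0], ds.latent_truth["child"]["factors"][:, 0])

    def test_population_covariance_oracle(self, big_dataset):
        cfg, ds = big_dataset
        emp = np.cov(np.vstack([ds.scores["mother"], ds.scores["father"]]),
                     rowvar=False)
        mc_se = 3.0 / np.sqrt(2 * cfg.n_trios)
        assert np.abs(emp - cfg.population_cov()).max() < 3 * mc_se

    def test_selection_shifts_parents_not_within(self):
        am = np.array([0.0, 0.0, 0.0, 0.4])
        cfg = tf.default_config(n_trios=100_000, seed=8,
                                selection_means_mother=am)
        ds = tf.simulate_trios(cfg)
        shift = cfg.loadings @ am
        se = 3.0 / np.sqrt(cfg.n_trios)
        assert np.abs(ds.scores["mother"].mean(axis=0) - shift).max() < 3 * se
        assert np.abs(ds.within_deviations().mean(axis=0)).max() < 3 * se

    def test_paired_seed_within_deviations_identical_under_selection(self):
        base = tf.default_config(n_trios=2000, seed=9)
        sel = tf.default_config(
            n_trios=2000, seed=9,
            selection_means_mother=np.array([0.0, 0.2, 0.0, 0.0]),
            selection_means_father=np.array([0.0, 0.0, 0.0, 0.3]),
        )
        np.testing.assert_allclose(
            tf.simulate_trios(base).within_deviations(),
            tf.simulate_trios(sel).within_deviations(),
        )

    def test_different_seeds_statistically_indistinguishable(self):
        a = tf.simulate_trios(tf.default_config(n_trios=5000, seed=21))
        b = tf.simulate_trios(tf.default_config(n_trios=5000, seed=22))
        _, p = stats.ks_2samp(a.scores["mother"][:, 0], b.scores["mother"][:, 0])
        assert p > 1e-3


class TestStandardize:
    def test_plain_zscoring(self):
        cfg = single_factor_config(n_trios=500, seed=3)
        ds = tf.simulate_trios(cfg)
        ds.scores["mother"][:, 0] = ds.scores["mother"][:, 0] * 2.0 + 5.0
        out = tf.standardize_panel(ds, reference="all")
        pooled = np.vstack([out.scores[r] for r in ("mother", "father", "child")])
        assert np.allclose(pooled.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(pooled.std(axis=0), 1.0, atol=1e-12)

    def test_covariate_equal_to_trait_raises(self):
        cfg = single_factor_config(n_trios=200, seed=4)
        ds = tf.simulate_trios(cfg)
        covs = {r: ds.scores[r][:, [0]] for r in ("mother", "father", "child")}
        with pytest.raises(ValueError, match="T1"):
            tf.standardize_panel(ds, covariates=covs)

    def test_residual_orthogonal_to_covariate(self, rng):
        cfg = single_factor_config(n_trios=1000, seed=5)
        ds = tf.simulate_trios(cfg)
        covs = {r: rng.standard_normal((1000, 1)) for r in
                ("mother", "father", "child")}
        for r in covs:
            ds.scores[r][:, 2] = 2.0 * covs[r][:, 0] + \
                0.1 * ds.scores[r][:, 2]
        out = tf.standardize_panel(ds, covariates=covs)
        pooled_y = np.concatenate([out.scores[r][:, 2] for r in covs])
        pooled_x = np.vstack([covs[r] for r in covs])[:, 0]
        assert abs(np.corrcoef(pooled_y, pooled_x)[0, 1]) < 1e-10
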