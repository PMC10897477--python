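import numpy as np
import pytest

import triofactor as tf
from triofactor.sem import FitResult, TrioModelSpec, fit_ml, residualize_child_on_parents

from conftest import single_factor_config

SIX = tuple(f"T{i+1}" for i in range(6))


@pytest.fixture(scope="module")
def one_factor_fit():
    cfg = single_factor_config(n_trios=200_000, seed=31)
    ds = tf.simulate_trios(cfg)
    pattern = np.sign(cfg.loadings)
    spec = tf.selection_means_spec(pattern, trait_labels=SIX,
                                   estimate_partner_cov=False)
    fr = fit_ml(spec, ds, n_starts=3, seed=0, compute_se=True)
    return cfg, spec, fr


class TestRecovery:
    def test_converged_with_se(self, one_factor_fit):
        _, _, fr = one_factor_fit
        assert fr.converged and fr.se is not None

    def test_loadings_within_3_se_of_truth(self, one_factor_fit):
        cfg, spec, fr = one_factor_fit
        sl = spec.slices()
        lam_hat = fr.theta[sl["lam"]]
        lam_se = fr.se[sl["lam"]]
        assert np.all(np.abs(lam_hat - cfg.loadings[:, 0]) < 3 * lam_se)

    def test_variances_and_means_recovered(self, one_factor_fit):
        cfg, spec, fr = one_factor_fit
        sl = spec.slices()
        assert abs(fr.theta[sl["psi"]][0] - 1.0) < 3 * fr.se[sl["psi"]][0]
        for key in ("alpha_m", "alpha_f"):
            assert abs(fr.theta[sl[key]][0]) < 3 * fr.se[sl[key]][0]

    def test_seed_stable(self, one_factor_fit):
        cfg, spec, _ = one_factor_fit
        ds = tf.simulate_trios(single_factor_config(n_trios=5000, seed=32))
        a = fit_ml(spec, ds, n_starts=2, seed=1, compute_se=False)
        b = fit_ml(spec, ds, n_starts=2, seed=1, compute_se=False)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_family_relabeling_invariant(self, one_factor_fit):
        cfg, spec, _ = one_factor_fit
        ds = tf.simulate_trios(single_factor_config(n_trios=3000, seed=33))
        X = ds.wide_array()
        perm = np.random.default_rng(0).permutation(X.shape[0])
        a = fit_ml(spec, X, n_starts=1, seed=0, compute_se=False)
        b = fit_ml(spec, X[perm], n_starts=1, seed=0, compute_se=False)
        # summation order of the sufficient statistics differs, so allow
        # optimizer-path noise
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-4, rtol=1e-4)


class TestFitMechanics:
    def test_bic_arithmetic(self):
        spec = TrioModelSpec(np.ones((6, 1)), trait_labels=SIX)
        kw = dict(spec=spec, theta=np.zeros(spec.n_params), se=None,
                  cov_params=None, converged=True, grad_norm=0.0, n_starts=1)
        a = FitResult(loglik=-100.0, n_params=10, n_trios=500, **kw)
        b = FitResult(loglik=-100.0, n_params=11, n_trios=500, **kw)
        assert b.bic - a.bic == pytest.approx(np.log(500))

    def test_saturated_model_loglik_bound(self):
        # the structural model can never beat the saturated Gaussian MLE
        ds = tf.simulate_trios(single_factor_config(n_trios=2000, seed=34))
        spec = tf.selection_means_spec(np.sign(
            single_factor_config(n_trios=2).loadings), trait_labels=SIX)
        fr = fit_ml(spec, ds, n_starts=2, seed=0, compute_se=False)
        sat, _ = tf.saturated_loglik(ds.wide_array())
        assert fr.loglik <= sat + 1e-6

    def test_underidentified_spec_raises(self):
        # two factors with identical single-indicator structure cannot be
        # separated
        pat = np.zeros((6, 2))
        pat[0, 0] = 1.0
        pat[0, 1] = 1.0
        spec = TrioModelSpec(pat, trait_labels=SIX)
        X = np.random.default_rng(1).standard_normal((50, 18))
        with pytest.raises(ValueError, match="under-identified"):
            fit_ml(spec, X, n_starts=1)

    def test_ci_brackets_estimate(self, one_factor_fit):
        _, _, fr = one_factor_fit
        cis = fr.ci()
        for name, est in fr.estimates.items():
            lo, hi = cis[name]
            assert lo <= est <= hi

    def test_summary_and_json_roundtrip(self, one_factor_fit, tmp_path):
        _, _, fr = one_factor_fit
        txt = fr.summary()
        assert "BIC" in txt and "psi[F1]" in txt
        fr.to_json(tmp_path / "fit.json")
        import json
        d = json.loads((tmp_path / "fit.json").read_text())
        assert d["converged"] and d["n_trios"] == fr.n_trios


class TestWithinRegression:
    def test_exact_midparent(self):
        cfg = single_factor_config(n_trios=300, seed=35)
        ds = tf.simulate_trios(cfg)
        ds.scores["child"] = 0.5 * (ds.scores["mother"] + ds.scores["father"])
        res = residualize_child_on_parents(ds)
        np.testing.assert_allclose(res.residuals.to_numpy(), 0.0, atol=1e-10)
        np.testing.assert_allclose(res.coefficients.loc["mother"], 0.5,
                                   atol=1e-10)
        np.testing.assert_allclose(res.coefficients.loc["father"], 0.5,
                                   atol=1e-10)

    def test_random_mating_coefficients_half(self, big_dataset):
        cfg, ds = big_dataset
        res = residualize_child_on_parents(ds)
        mc_se = 3.0 / np.sqrt(cfg.n_trios)
        assert np.abs(res.coefficients.loc["mother"] - 0.5).max() < 3 * mc_se
        assert np.abs(res.coefficients.loc["father"] - 0.5).max() < 3 * mc_se

    def test_residual_covariance_half_population(self, big_dataset):
        cfg, ds = big_dataset
        res = residualize_child_on_parents(ds)
        emp = np.cov(res.residuals.to_numpy(), rowvar=False)
        mc_se = 3.0 / np.sqrt(cfg.n_trios)
        assert np.abs(emp - 0.5 * cfg.population_cov()).max() < 3 * mc_se

    def test_collinear_parents_named(self):
        cfg = single_factor_config(n_trios=100, seed=36)
        ds = tf.simulate_trios(cfg)
        ds.scores["father"][:, 1] = ds.scores["mother"][:, 1]
        with pytest.raises(ValueError, match="T2"):
            residualize_child_on_parents(ds)


class TestBiasProperty:
    def test_within_family_estimates_unbiased_under_selection_and_assortment(self):
        """Core design property: switching selection + assortment ON leaves
        within-family structure unchanged (paired seeds)."""
        clean = tf.default_config(n_trios=20_000, seed=37)
        biased = tf.default_config(
            n_trios=20_000, seed=37,
            partner_cross_cov=np.diag([0.0, 0.0, 0.081, 0.257]),
            selection_means_mother=np.array([0.0, 0.035, 0.037, 0.0]),
            selection_means_father=np.array([0.0, 0.0, 0.0, 0.183]),
        )
        ds_c, ds_b = tf.simulate_trios(clean), tf.simulate_trios(biased)
        # between-family (parental) moments shift ...
        shift = np.abs(ds_b.scores["father"].mean(axis=0)
                       - ds_c.scores["father"].mean(axis=0))
        assert shift.max() > 0.01
        # ... while the within-family layer is essentially unchanged
        dev_c, dev_b = ds_c.within_deviations(), ds_b.within_deviations()
        np.testing.assert_allclose(dev_c.mean(axis=0), dev_b.mean(axis=0),
                                   atol=5e-3)
        Sc = np.cov(dev_c, rowvar=False)
        Sb = np.cov(dev_b, rowvar=False)
        assert np.abs(Sc - Sb).max() < 9.0 / np.sqrt(20_000)
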