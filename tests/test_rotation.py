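import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import triofactor as tf
from triofactor.rotation import (
    RotationSolution,
    bifactor_geomin_rotate,
    geomin_criterion,
    geomin_rotate,
    match_factors,
    simple_structure_from_rotation,
)


def _random_orth(k, seed):
    q, r = np.linalg.qr(np.random.default_rng(seed).standard_normal((k, k)))
    return q * np.sign(np.diag(r))


@pytest.fixture(scope="module")
def table_loadings():
    return tf.efa_loadings_5factor().to_numpy()


def simple_structure_matrix():
    L = np.zeros((9, 3))
    L[:3, 0] = [0.8, 0.7, 0.6]
    L[3:6, 1] = [0.7, 0.6, 0.5]
    L[6:, 2] = [0.8, 0.5, 0.4]
    return L


class TestGeomin:
    def test_perfect_simple_structure_is_fixed_point(self):
        L = simple_structure_matrix()
        sol = geomin_rotate(L, n_starts=10, random_state=0)
        aligned, *_ = match_factors(sol.rotated_loadings, L)
        assert np.abs(aligned - L).max() < 0.02
        f0, _ = geomin_criterion(L, 0.01)
        assert sol.criterion_value <= f0 + 1e-8

    def test_criterion_matches_heavy_restart_oracle(self):
        A = np.random.default_rng(10).standard_normal((11, 3)) * 0.4
        fast = geomin_rotate(A, n_starts=30, random_state=1)
        oracle = geomin_rotate(A, n_starts=200, random_state=2)
        assert fast.criterion_value == pytest.approx(
            oracle.criterion_value, abs=1e-5)

    def test_large_epsilon_flattens_objective(self):
        A = np.random.default_rng(11).standard_normal((8, 3)) * 0.5
        eps = 1e6
        vals = []
        for s in range(5):
            T = _random_orth(3, s)
            f, _ = geomin_criterion(A @ T, eps)
            vals.append(f)
        assert (max(vals) - min(vals)) / max(vals) < 1e-5

    def test_fit_preserved_oblique(self):
        rng = np.random.default_rng(12)
        for s in range(5):
            A = rng.standard_normal((10, 3)) * 0.5
            sol = geomin_rotate(A, n_starts=10, random_state=s)
            lhs = sol.rotated_loadings @ sol.factor_correlations @ \
                sol.rotated_loadings.T
            assert np.abs(lhs - A @ A.T).max() < 1e-8

    def test_monotone_descent(self):
        A = np.random.default_rng(13).standard_normal((11, 4)) * 0.4
        sol = geomin_rotate(A, n_starts=1, random_state=0)
        h = np.array(sol.history)
        assert (np.diff(h) <= 1e-10).all()

    def test_requires_two_factors(self):
        with pytest.raises(ValueError, match="2 factors"):
            geomin_rotate(np.ones((5, 1)))


class TestBifactorGeomin:
    def test_bifactor_form_is_fixed_point(self, table_loadings):
        L = table_loadings
        sol = bifactor_geomin_rotate(L, n_starts=10, random_state=0)
        aligned, *_ = match_factors(sol.rotated_loadings, L)
        assert np.abs(aligned - L).max() < 0.02

    def test_recovery_from_random_rotation(self, table_loadings):
        L = table_loadings
        sol = bifactor_geomin_rotate(L @ _random_orth(5, 3), n_starts=30,
                                     random_state=0)
        aligned, *_ = match_factors(sol.rotated_loadings, L)
        # general-factor column nearly perfectly recovered
        g_corr = np.corrcoef(aligned[:, 0], L[:, 0])[0, 1]
        assert g_corr > 0.99
        assert np.abs(aligned - L).max() < 0.05

    def test_orthogonality_and_fit_preserved(self, table_loadings):
        sol = bifactor_geomin_rotate(table_loadings, n_starts=5, random_state=1)
        np.testing.assert_allclose(sol.factor_correlations, np.eye(5))
        T = sol.rotation_matrix
        np.testing.assert_allclose(T @ T.T, np.eye(5), atol=1e-10)
        lhs = sol.rotated_loadings @ sol.rotated_loadings.T
        assert np.abs(lhs - table_loadings @ table_loadings.T).max() < 1e-8

    def test_sign_convention(self, table_loadings):
        sol = bifactor_geomin_rotate(table_loadings @ _random_orth(5, 7),
                                     n_starts=10, random_state=2)
        L = sol.rotated_loadings
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0


@settings(max_examples=8, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(2, 5))
def test_rotation_preserves_common_variance_property(seed, k):
    """Any rotation of any loading matrix reproduces the unrotated common
    covariance: Λ_rot Φ Λ_rotᵀ = Λ₀Λ₀ᵀ to 1e-8."""
    A = np.random.default_rng(seed).standard_normal((11, k)) * 0.5
    for sol in (geomin_rotate(A, n_starts=3, random_state=0),
                bifactor_geomin_rotate(A, n_starts=3, random_state=0)):
        lhs = sol.rotated_loadings @ sol.factor_correlations @ \
            sol.rotated_loadings.T
        assert np.abs(lhs - A @ A.T).max() < 1e-8


class TestSimpleStructure:
    def test_threshold_rule(self):
        L = np.array([[0.5, 0.05], [0.05, 0.5], [0.5, 0.05]])
        sol = RotationSolution(L, np.eye(2), 0.0, np.eye(2), True, 1)
        pat = simple_structure_from_rotation(sol, rule=0.1)
        assert (pat[np.abs(L) < 0.1] == 0).all()
        assert (pat[np.abs(L) >= 0.1] != 0).all()

    def test_packaged_pattern_passthrough_and_drop(self, table_loadings):
        sol = RotationSolution(table_loadings, np.eye(5), 0.0, np.eye(5),
                               True, 1)
        bold = tf.cfa_simple_structure()
        pat = simple_structure_from_rotation(sol, pattern=bold.to_numpy())
        np.testing.assert_array_equal(pat, bold.to_numpy())
        # automatic rule: dropping the depression residual factor leaves a
        # four-factor pattern
        pat4 = simple_structure_from_rotation(sol, rule=0.1, drop=(4,))
        assert pat4.shape == (11, 4)

    def test_empty_factor_raises(self):
        L = np.array([[0.5, 0.0], [0.6, 0.0], [0.4, 0.0]])
        sol = RotationSolution(L, np.eye(2), 0.0, np.eye(2), True, 1)
        with pytest.raises(ValueError, match="no retained indicators"):
            simple_structure_from_rotation(sol, rule=0.1)
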