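"""Scikit-learn style estimators over the factor-analysis and trio-SEM core.

All estimators follow the sklearn contract: constructor stores
hyperparameters untouched, ``fit`` validates input and sets trailing-
underscore attributes, ``get_params``/``set_params`` come from
``BaseEstimator`` so the classes compose with sklearn model selection.
``X`` is either a ``TrioDataset`` or a wide (n, 33) array in
mother/father/child block order for the trio models, and a plain (n, p)
matrix for ``MLFactorAnalysis``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from . import efa as _efa
from . import pipeline as _pipe
from . import rotation as _rot
from .datasets import TrioDataset


def _as_wide(X) -> np.ndarray:
    if isinstance(X, TrioDataset):
        return X.wide_array()
    return check_array(X, ensure_min_features=3)


class MLFactorAnalysis(BaseEstimator):
    """Maximum-likelihood exploratory factor analysis.

    Parameters
    ----------
    n_factors : int
        Number of common factors to extract (canonical unrotated solution).
    rotation : {None, "geomin", "bifactor-geomin"}
        Optional rotation applied after extraction.
    epsilon : float
        Geomin smoothing constant.
    n_starts : int
        Random rotation starts.
    """

    def __init__(self, n_factors: int = 1, rotation: str | None = None,
                 epsilon: float = 0.01, n_starts: int = 30,
                 random_state=None):
        self.n_factors = n_factors
        self.rotation = rotation
        self.epsilon = epsilon
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        S = np.cov(X, rowvar=False, bias=True)
        return self.fit_from_cov(S, n_obs=X.shape[0])

    def fit_from_cov(self, S, n_obs: int):
        res = _efa.extract_efa(np.asarray(S, float), self.n_factors, n_obs)
        self.loadings_ = res.loadings
        self.uniquenesses_ = res.uniquenesses
        self.loglik_ = res.loglik
        self.bic_ = res.bic
        self.n_params_ = res.n_params
        self.converged_ = res.converged
        if self.rotation is not None and self.n_factors >= 2:
            fn = {"geomin": _rot.geomin_rotate,
                  "bifactor-geomin": _rot.bifactor_geomin_rotate}[self.rotation]
            sol = fn(res.loadings, epsilon=self.epsilon,
                     n_starts=self.n_starts, random_state=self.random_state)
            self.rotation_ = sol
            self.loadings_ = sol.rotated_loadings
            self.factor_correlations_ = sol.factor_correlations
        return self

    def get_covariance(self):
        check_is_fitted(self, "loadings_")
        phi = getattr(self, "factor_correlations_", np.eye(self.n_factors))
        return self.loadings_ @ phi @ self.loadings_.T + np.diag(self.uniquenesses_)


class GeominRotator(BaseEstimator):
    """Geomin / bi-factor geomin rotation of a fixed loading matrix.

    ``fit`` takes the unrotated p x k loadings as ``X``; ``transform``
    applies the fitted rotation matrix to compatible loadings.
    """

    def __init__(self, bifactor: bool = True, epsilon: float = 0.01,
                 n_starts: int = 30, random_state=None):
        self.bifactor = bifactor
        self.epsilon = epsilon
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        fn = _rot.bifactor_geomin_rotate if self.bifactor else _rot.geomin_rotate
        sol = fn(X, epsilon=self.epsilon, n_starts=self.n_starts,
                 random_state=self.random_state)
        self.solution_ = sol
        self.loadings_ = sol.rotated_loadings
        self.factor_correlations_ = sol.factor_correlations
        self.rotation_ = sol.rotation_matrix
        self.criterion_ = sol.criterion_value
        self.converged_ = sol.converged
        return self

    def transform(self, X):
        check_is_fitted(self, "rotation_")
        X = check_array(X)
        T = self.rotation_
        if self.bifactor:
            return X @ T
        return X @ np.linalg.inv(T).T

    def fit_transform(self, X, y=None):
        return self.fit(X).loadings_


class TrioCFA(BaseEstimator):
    """Confirmatory trio SEM with meiosis-fixed 0.5 transmission paths.

    Parameters
    ----------
    model : {"assortment", "selection_means"}
        ``assortment``: within-family factor variance fixed to 1, free
        mother-father latent covariances; fitted attribute
        ``partner_correlations_`` reports standardized b per factor.
        ``selection_means``: within-family variance fixed to 0.5 and mean
        to 0; fitted attributes ``latent_means_mother_`` /
        ``latent_means_father_``.
    pattern : DataFrame or array, optional
        Signed simple-structure loading pattern; defaults to the packaged
        confirmatory bifactor pattern.
    """

    def __init__(self, model: str = "assortment", pattern=None,
                 n_starts: int = 10, seed: int = 0, compute_se: bool = True,
                 estimate_partner_cov: bool = True, gtol: float = 1e-6,
                 maxiter: int = 2000):
        self.model = model
        self.pattern = pattern
        self.n_starts = n_starts
        self.seed = seed
        self.compute_se = compute_se
        self.estimate_partner_cov = estimate_partner_cov
        self.gtol = gtol
        self.maxiter = maxiter

    def fit(self, X, y=None):
        Xw = _as_wide(X)
        if Xw.shape[1] % 3:
            raise ValueError("wide trio data must have 3p columns")
        kw = dict(n_starts=self.n_starts, seed=self.seed,
                  compute_se=self.compute_se, gtol=self.gtol,
                  maxiter=self.maxiter)
        if self.model == "assortment":
            fr, table = _pipe.fit_cfa_assortment(Xw, pattern=self.pattern, **kw)
            self.partner_correlations_ = table
        elif self.model == "selection_means":
            fr, table = _pipe.fit_cfa_selection_means(
                Xw, pattern=self.pattern,
                estimate_partner_cov=self.estimate_partner_cov, **kw)
            self.latent_means_ = table
            self.latent_means_mother_ = table.set_index("factor")["alpha_mother"]
            self.latent_means_father_ = table.set_index("factor")["alpha_father"]
        else:
            raise ValueError(f"unknown model {self.model!r}")
        self.result_ = fr
        sl = fr.spec.slices()
        self.loadings_ = fr.spec.unpack(fr.theta)["lam"]
        self.factor_variances_ = fr.theta[sl["psi"]]
        self.residual_variances_ = fr.theta[sl["theta"]]
        self.loglik_ = fr.loglik
        self.bic_ = fr.bic
        self.converged_ = fr.converged
        return self

    def score(self, X, y=None):
        """Average per-trio log-likelihood at the fitted parameters."""
        check_is_fitted(self, "result_")
        from .sem import loglik
        Xw = _as_wide(X)
        return loglik(self.result_.spec, self.result_.theta, Xw) / Xw.shape[0]


class SequentialEFA(BaseEstimator):
    """Sequential between/within EFA search with BIC selection + rotation."""

    def __init__(self, max_factors: int = 6, rotate: bool = True,
                 epsilon: float = 0.01, n_starts: int = 30, random_state=None):
        self.max_factors = max_factors
        self.rotate = rotate
        self.epsilon = epsilon
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y=None):
        if not isinstance(X, TrioDataset):
            Xw = check_array(X)
            p = Xw.shape[1] // 3
            X = TrioDataset({"mother": Xw[:, :p], "father": Xw[:, p:2 * p],
                             "child": Xw[:, 2 * p:]},
                            trait_labels=[f"V{i + 1}" for i in range(p)])
        ledger = _pipe.sequential_efa_search(X, max_k=self.max_factors)
        self.ledger_ = ledger
        self.best_index_ = ledger.best_index
        row = ledger.table.loc[self.best_index_]
        self.n_factors_between_ = int(row["k_between"])
        self.n_factors_within_ = int(row["k_within"])
        self.equal_structure_ = bool(row["equal_structure"])
        self.loadings_ = ledger.best.loadings_between
        if self.rotate and self.n_factors_between_ >= 2:
            sol = _pipe.rotate_best_model(
                ledger, epsilon=self.epsilon, n_starts=self.n_starts,
                random_state=self.random_state)
            self.rotation_ = sol
            self.rotated_loadings_ = sol.rotated_loadings
        return self
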