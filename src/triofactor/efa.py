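"""Maximum-likelihood exploratory factor extraction.

Single-level extraction uses the classic profile approach: for fixed
uniquenesses Θ the optimal loadings have a closed form through the
eigendecomposition of Θ^{-1/2} S Θ^{-1/2}, leaving a p-dimensional
optimization over log-uniquenesses. The ML discrepancy

    F(S, Σ) = log|Σ| - log|S| + tr(Σ⁻¹ S) - p

relates to the log-likelihood as  ll = ll_saturated - (n/2) F, which is how
BIC values are computed.

The two-level fit handles the between-family (parental) and within-family
(child-minus-midparent, rescaled to the population metric) covariance
layers jointly, optionally constraining the loading matrices equal across
levels (metric invariance, echelon-identified loadings); residual variances
stay level-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)

MIN_UNIQUENESS = 1e-4


@dataclass
class EFAResult:
    """Unrotated ML factor solution for one covariance matrix."""

    loadings: np.ndarray  # p x k
    uniquenesses: np.ndarray  # p
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    discrepancy: float

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.loglik


def _n_efa_params(p: int, k: int) -> int:
    # loadings identified up to rotation + uniquenesses
    return p * k - k * (k - 1) // 2 + p


def _sat_const(S: np.ndarray, n: int) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular")
    return -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)


def _profile(S: np.ndarray, k: int, psi: np.ndarray):
    """Profile discrepancy over loadings at fixed uniquenesses."""
    d = 1.0 / np.sqrt(psi)
    A = S * np.outer(d, d)
    w, V = np.linalg.eigh(A)
    w, V = w[::-1], V[:, ::-1]
    F = np.sum(w[k:] - np.log(np.maximum(w[k:], 1e-300)) - 1.0)
    return F, w, V


def _profile_loadings(S, k, psi):
    _, w, V = _profile(S, k, psi)
    scale = np.sqrt(np.maximum(w[:k] - 1.0, 0.0))
    return np.sqrt(psi)[:, None] * V[:, :k] * scale


def extract_efa(cov_matrix: np.ndarray, k: int, n_obs: int) -> EFAResult:
    """ML extraction of ``k`` factors from a covariance matrix.

    Heywood cases are handled by bounding uniquenesses at
    ``MIN_UNIQUENESS`` times the observed variance (with a warning).
    ``k = 0`` returns the diagonal (independence) model, whose MLE is
    closed-form.
    """
    S = np.asarray(cov_matrix, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("cov_matrix must be symmetric")
    if k >= p:
        raise ValueError(f"k must be < {p}")
    sat = _sat_const(S, n_obs)
    if k == 0:
        psi = np.diag(S).copy()
        F, *_ = _profile(S, 0, psi)
        ll = sat - 0.5 * n_obs * F
        return EFAResult(np.zeros((p, 0)), psi, ll, p, n_obs, True, F)

    diagS = np.diag(S)
    start = (1.0 - 0.5 * k / p) / np.diag(np.linalg.inv(S)) if \
        np.linalg.matrix_rank(S) == p else 0.5 * diagS
    lo = np.log(MIN_UNIQUENESS * diagS)
    hi = np.log(2.0 * diagS)

    def obj(z):
        psi = np.exp(z)
        F, w, V = _profile(S, k, psi)
        # analytic profile gradient: dF/dψ_i = [Σ⁻¹(Σ−S)Σ⁻¹]_ii at the
        # profiled loadings; chain rule onto the log scale
        scale = np.sqrt(np.maximum(w[:k] - 1.0, 0.0))
        lam = np.sqrt(psi)[:, None] * V[:, :k] * scale
        sigma = lam @ lam.T + np.diag(psi)
        si = np.linalg.inv(sigma)
        grad = np.diag(si @ (sigma - S) @ si) * psi
        return F, grad

    # two deterministic starts: the classical 1/diag(S⁻¹) heuristic and the
    # full-uniqueness point. Near-diagonal S has a degenerate ML set (common
    # variance can absorb uniqueness with no change in fit); ties are broken
    # toward the maximal-uniqueness (most parsimonious) solution.
    res = None
    for st in (start, diagS):
        cand = optimize.minimize(
            obj, np.log(np.clip(st, np.exp(lo), np.exp(hi))), jac=True,
            method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": 1000, "gtol": 1e-12, "ftol": 1e-15},
        )
        if res is None or cand.fun < res.fun - 1e-10 or (
            abs(cand.fun - res.fun) <= 1e-10
            and cand.x.sum() > res.x.sum()
        ):
            res = cand
    psi = np.exp(res.x)
    at_bound = res.x <= lo + 1e-6
    if at_bound.any():
        logger.warning("Heywood case: uniqueness at lower bound for "
                       "variable(s) %s", np.flatnonzero(at_bound).tolist())
    lam = _profile_loadings(S, k, psi)
    F = float(res.fun)
    ll = sat - 0.5 * n_obs * F
    return EFAResult(lam, psi, ll, _n_efa_params(p, k), n_obs,
                     bool(res.success), F)


# ----------------------------------------------------------------------
def _echelon(lam: np.ndarray) -> np.ndarray:
    """Rotate loadings so the leading k x k block is lower triangular."""
    p, k = lam.shape
    if k == 0:
        return lam
    q, r = np.linalg.qr(lam[:k, :].T)
    out = lam @ q
    sign = np.sign(np.diag(out[:k, :]))
    sign[sign == 0] = 1.0
    return out * sign


def _ml_discrepancy(S, sigma):
    p = S.shape[0]
    cf = linalg.cho_factor(sigma, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    trace = np.trace(linalg.cho_solve(cf, S, check_finite=False))
    sign, logdetS = np.linalg.slogdet(S)
    return logdet - logdetS + trace - p


@dataclass
class TwoLevelEFAResult:
    """Joint between/within exploratory fit (optionally metric-equal)."""

    loadings_between: np.ndarray
    loadings_within: np.ndarray
    uniquenesses_between: np.ndarray
    uniquenesses_within: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    equal_loadings: bool


def fit_two_level_efa(
    S_between: np.ndarray,
    n_between: int,
    S_within: np.ndarray,
    n_within: int,
    k_between: int,
    k_within: int,
    equal_loadings: bool = False,
) -> TwoLevelEFAResult:
    """Fit EFA models to the two covariance layers.

    Without the equality constraint the levels are independent and each is
    fit by the profile method. With ``equal_loadings`` (requires
    ``k_between == k_within``) a joint likelihood is maximized over one
    echelon-identified loading matrix and level-specific uniquenesses.
    """
    N = n_between + n_within
    if not equal_loadings:
        rb = extract_efa(S_between, k_between, n_between)
        rw = extract_efa(S_within, k_within, n_within)
        return TwoLevelEFAResult(
            rb.loadings, rw.loadings, rb.uniquenesses, rw.uniquenesses,
            rb.loglik + rw.loglik, rb.n_params + rw.n_params, N,
            rb.converged and rw.converged, False,
        )
    if k_between != k_within:
        raise ValueError("equal_loadings requires equal factor counts")
    k = k_between
    p = S_between.shape[0]
    S_pool = (n_between * S_between + n_within * S_within) / N
    init = extract_efa(S_pool, k, N)
    lam0 = _echelon(init.loadings)
    tril = [(i, j) for j in range(k) for i in range(p) if i >= j]
    rows = np.array([i for i, _ in tril])
    cols = np.array([j for _, j in tril])

    sat = _sat_const(S_between, n_between) + _sat_const(S_within, n_within)
    lo_b = np.log(MIN_UNIQUENESS * np.diag(S_between))
    lo_w = np.log(MIN_UNIQUENESS * np.diag(S_within))

    def unpack(z):
        lam = np.zeros((p, k))
        lam[rows, cols] = z[: len(tril)]
        pb = np.exp(np.clip(z[len(tril): len(tril) + p], lo_b, 30))
        pw = np.exp(np.clip(z[len(tril) + p:], lo_w, 30))
        return lam, pb, pw

    def obj(z):
        lam, pb, pw = unpack(z)
        common = lam @ lam.T
        try:
            fb = _ml_discrepancy(S_between, common + np.diag(pb))
            fw = _ml_discrepancy(S_within, common + np.diag(pw))
        except linalg.LinAlgError:
            return 1e10
        return (n_between * fb + n_within * fw) / N

    z0 = np.concatenate([
        lam0[rows, cols],
        np.log(np.clip(init.uniquenesses, 1e-3, None)),
        np.log(np.clip(init.uniquenesses, 1e-3, None)),
    ])
    res = optimize.minimize(obj, z0, method="L-BFGS-B",
                            options={"maxiter": 2000, "gtol": 1e-8})
    lam, pb, pw = unpack(res.x)
    ll = sat - 0.5 * N * float(res.fun)
    n_params = len(tril) + 2 * p
    return TwoLevelEFAResult(lam, lam, pb, pw, ll, n_params, N,
                             bool(res.success), True)
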