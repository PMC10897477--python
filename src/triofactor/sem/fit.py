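"""Maximum-likelihood fitting of the trio model.

Quasi-Newton (L-BFGS-B) maximization on a transformed scale (variances on
the log scale, so Heywood excursions cannot crash the likelihood), with
multi-start: the first start is the spec's deterministic initial point,
subsequent starts jitter loadings (including random sign flips, since
factor signs are only locally identified). Standard errors come from the
observed information (central finite-difference Hessian of the negative
log-likelihood on the raw scale) inverted at the optimum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .likelihood import _loglik_stats, suff_stats
from .moments import implied_moments
from .spec import TrioModelSpec

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of one ML fit."""

    spec: TrioModelSpec
    theta: np.ndarray
    se: np.ndarray | None
    cov_params: np.ndarray | None
    loglik: float
    n_params: int
    n_trios: int
    converged: bool
    grad_norm: float
    n_starts: int
    hessian_condition: float | None = None

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_trios) - 2.0 * self.loglik

    @property
    def names(self) -> list[str]:
        return self.spec.param_names()

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.names, self.theta.tolist()))

    def ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Wald intervals, estimate ± z·SE."""
        if self.se is None:
            raise ValueError("standard errors unavailable (fit not converged "
                             "or information matrix not positive definite)")
        from scipy import stats
        z = stats.norm.ppf(0.5 + level / 2.0)
        return {
            nm: (est - z * s, est + z * s)
            for nm, est, s in zip(self.names, self.theta, self.se)
        }

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "se": None if self.se is None else dict(zip(self.names, self.se.tolist())),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_trios": self.n_trios,
            "bic": self.bic,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_starts": self.n_starts,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"ML fit: loglik={self.loglik:.3f}  BIC={self.bic:.3f}  "
            f"n={self.n_trios}  params={self.n_params}  "
            f"converged={self.converged}",
            f"{'parameter':<22}{'estimate':>10}{'se':>10}",
        ]
        for i, nm in enumerate(self.names):
            s = f"{self.se[i]:>10.4f}" if self.se is not None else "        --"
            lines.append(f"{nm:<22}{self.theta[i]:>10.4f}{s}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
def _check_identification(spec: TrioModelSpec, theta0: np.ndarray) -> None:
    """Rank of the finite-difference Jacobian of the implied moments.

    Evaluated at a generic admissible point rather than at the initial
    values: the moment map can lose rank on measure-zero submanifolds
    (e.g. exactly at the random-mating equilibrium ψ = 2ψ_w with γ = 0,
    where a two-indicator specific factor's loading/residual split is
    locally flat) without the model being structurally under-identified.
    """
    rng = np.random.default_rng(12345)
    theta0 = theta0 + 0.1 + 0.05 * rng.standard_normal(theta0.size)

    def moments_vec(th):
        m = implied_moments(spec, th)
        iu = np.triu_indices(m.cov.shape[0])
        return np.concatenate([m.mean, m.cov[iu]])

    f0 = moments_vec(theta0)
    J = np.empty((f0.size, theta0.size))
    for j in range(theta0.size):
        h = 1e-5 * (1.0 + abs(theta0[j]))
        tp, tm = theta0.copy(), theta0.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (moments_vec(tp) - moments_vec(tm)) / (2 * h)
    rank = np.linalg.matrix_rank(J, tol=1e-8 * max(1.0, np.abs(J).max()))
    if rank < theta0.size:
        raise ValueError(
            f"model is under-identified: moment Jacobian rank {rank} < "
            f"{theta0.size} free parameters"
        )


def _jittered_start(spec: TrioModelSpec, base: np.ndarray, rng) -> np.ndarray:
    th = base.copy()
    sl = spec.slices()
    lam = th[sl["lam"]]
    flip = np.where(rng.random(lam.size) < 0.15, -1.0, 1.0)
    th[sl["lam"]] = lam * flip * rng.uniform(0.4, 1.6, lam.size) + \
        rng.normal(0.0, 0.05, lam.size)
    if spec.estimate_partner_cov:
        th[sl["gamma"]] = rng.normal(0.0, 0.05, th[sl["gamma"]].size)
    if spec.estimate_latent_means:
        for key in ("alpha_m", "alpha_f"):
            th[sl[key]] = rng.normal(0.0, 0.1, th[sl[key]].size)
    return th


def _canonicalize_signs(spec: TrioModelSpec, theta: np.ndarray) -> np.ndarray:
    """Flip each factor so the sum of its pattern-signed loadings is positive.

    The likelihood is invariant to jointly flipping a factor's loadings,
    latent means and partner-covariance row/column (diagonal Γ is sign
    invariant), so replicate averages of signed quantities need a fixed
    convention. The pattern's signs are honoured: a factor matching the
    pattern with all signs reversed is flipped back.
    """
    theta = theta.copy()
    b = spec.unpack(theta)
    sl = spec.slices()
    lam_free = theta[sl["lam"]].copy()
    idx = spec._free_idx
    pat_sign = np.sign(spec.pattern[idx[:, 0], idx[:, 1]])
    am = theta[sl["alpha_m"]].copy() if spec.estimate_latent_means else None
    af = theta[sl["alpha_f"]].copy() if spec.estimate_latent_means else None
    for j in range(spec.n_factors):
        col = idx[:, 1] == j
        if np.sum(lam_free[col] * pat_sign[col]) < 0:
            lam_free[col] *= -1.0
            if am is not None:
                am[j] *= -1.0
                af[j] *= -1.0
    theta[sl["lam"]] = lam_free
    if am is not None:
        theta[sl["alpha_m"]] = am
        theta[sl["alpha_f"]] = af
    return theta


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f(x) + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4.0 * h[i] * h[j])
    return H


def fit_ml(
    spec: TrioModelSpec,
    data,
    init: np.ndarray | None = None,
    n_starts: int = 10,
    seed: int = 0,
    compute_se: bool = True,
    gtol: float = 1e-6,
    maxiter: int = 2000,
    check_identification: bool = True,
) -> FitResult:
    """Fit the trio model by maximum likelihood.

    Parameters
    ----------
    data : TrioDataset or (n, 33) array
        Complete trios, wide block order mother/father/child.
    init : array, optional
        Raw-scale starting values; defaults to the spec's initial point.
    n_starts : int
        Multi-start count (first start deterministic, rest jittered);
        the best log-likelihood wins.
    """
    n, xbar, S0 = suff_stats(data)
    theta0 = spec.init_theta() if init is None else np.asarray(init, float)
    if check_identification:
        _check_identification(spec, theta0)

    def negll(z):
        return -_loglik_stats(spec, spec.from_optim(z), n, xbar, S0) / n

    rng = np.random.default_rng(seed)
    best = None
    n_done = 0
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else _jittered_start(spec, theta0, rng)
        res = optimize.minimize(
            negll,
            spec.to_optim(start),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "maxfun": 10 * maxiter},
        )
        n_done += 1
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    theta_hat = _canonicalize_signs(spec, spec.from_optim(best.x))
    ll = _loglik_stats(spec, theta_hat, n, xbar, S0)
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    converged = bool(best.success) or grad_norm < 1e-3
    if not converged:
        logger.warning("fit_ml did not converge after %d starts: %s",
                       n_done, best.message)

    se = cov_params = cond = None
    if compute_se and converged:
        def negll_raw(th):
            return -_loglik_stats(spec, th, n, xbar, S0)

        H = _fd_hessian(negll_raw, theta_hat)
        eig = np.linalg.eigvalsh(H)
        if eig.min() > 1e-10 * max(1.0, eig.max()):
            cov_params = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov_params))
            cond = float(eig.max() / eig.min())
        else:
            # near-flat directions (e.g. loading/residual split of a
            # two-indicator factor close to the equilibrium manifold):
            # pseudo-inverse covariance; SEs in flat directions are
            # reported as inf.
            logger.warning("observed information nearly singular; using "
                           "pseudo-inverse for standard errors")
            cov_params = np.linalg.pinv(H, rcond=1e-10)
            d = np.diag(cov_params).copy()
            null = np.abs(
                np.linalg.eigh(H)[1][:, eig < 1e-10 * max(1.0, eig.max())]
            ).max(axis=1) > 0.5
            d[null] = np.inf
            se = np.sqrt(np.abs(d))
            cond = np.inf

    return FitResult(
        spec=spec,
        theta=theta_hat,
        se=se,
        cov_params=cov_params,
        loglik=float(ll),
        n_params=spec.n_params,
        n_trios=n,
        converged=converged,
        grad_norm=grad_norm,
        n_starts=n_done,
        hessian_condition=cond,
    )
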