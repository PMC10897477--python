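"""Gaussian likelihood of the trio model via sufficient statistics.

The 33-dimensional Gaussian log-likelihood depends on the data only through
the sample mean and covariance, so evaluation cost is independent of the
number of trios. Implied covariances are factorized (Cholesky); an explicit
inverse is never formed. A singular implied covariance yields a large
negative, optimizer-safe penalty rather than NaN.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import linalg

from .moments import implied_moments
from .spec import TrioModelSpec

logger = logging.getLogger(__name__)

_PENALTY = -1e12


def suff_stats(data) -> tuple[int, np.ndarray, np.ndarray]:
    """(n, mean, covariance-with-divisor-n) of wide trio data.

    Accepts a ``TrioDataset`` or an (n, 3p) array in mother/father/child
    block order.
    """
    X = data.wide_array() if hasattr(data, "wide_array") else np.asarray(data, float)
    n = X.shape[0]
    xbar = X.mean(axis=0)
    xc = X - xbar
    S0 = xc.T @ xc / n
    return n, xbar, S0


def _loglik_stats(spec: TrioModelSpec, theta, n, xbar, S0) -> float:
    mom = implied_moments(spec, theta)
    sigma = mom.cov
    d = sigma.shape[0]
    try:
        cf = linalg.cho_factor(sigma, lower=True, check_finite=False)
    except linalg.LinAlgError:
        eigmin = float(np.linalg.eigvalsh(sigma).min())
        logger.warning("singular implied covariance (min eig %.3e); penalized", eigmin)
        return _PENALTY * (1.0 + abs(eigmin))
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    trace = np.trace(linalg.cho_solve(cf, S0, check_finite=False))
    quad = 0.0
    if spec.estimate_latent_means:
        dev = xbar - mom.mean
        quad = float(dev @ linalg.cho_solve(cf, dev, check_finite=False))
    return -0.5 * n * (d * np.log(2.0 * np.pi) + logdet + trace + quad)


def loglik(spec: TrioModelSpec, theta, data) -> float:
    """Sum over trios of the 33-dimensional Gaussian log-density.

    When the spec does not model latent means the observed means are
    saturated (profiled at the sample mean), which matches standardized
    input scores.
    """
    n, xbar, S0 = suff_stats(data)
    return _loglik_stats(spec, theta, n, xbar, S0)


def saturated_loglik(data) -> tuple[float, int]:
    """Log-likelihood and parameter count of the saturated Gaussian model.

    The MLE sets μ = x̄ and Σ = S (divisor n), giving
    ``-n/2 (d log 2π + log|S| + d)``.
    """
    n, _, S0 = suff_stats(data)
    d = S0.shape[0]
    sign, logdet = np.linalg.slogdet(S0)
    if sign <= 0:
        raise ValueError("sample covariance is singular")
    ll = -0.5 * n * (d * np.log(2.0 * np.pi) + logdet + d)
    return ll, d + d * (d + 1) // 2
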