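"""Geomin and bi-factor geomin rotation by gradient projection.

The geomin complexity of a loading matrix Λ (p x k) is

    f(Λ) = Σ_i ( Π_j (λ_ij² + ε) )^{1/k},

a smoothed row-wise product criterion whose minimization drives each row
toward simple structure. Plain geomin is performed over oblique rotations;
the bi-factor variant applies the geomin criterion to columns 2..k only
(column 1 is the unpenalized general factor) and rotates over the
orthogonal group, so the general factor and the specific subfactors are all
mutually uncorrelated. Both use the gradient-projection algorithm with
monotone backtracking and random orthonormal restarts (geomin is known to
have local minima).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)


@dataclass
class RotationSolution:
    """Converged (or best-found) rotated solution."""

    rotated_loadings: np.ndarray
    factor_correlations: np.ndarray  # identity for orthogonal rotations
    criterion_value: float
    rotation_matrix: np.ndarray
    converged: bool
    n_random_starts: int
    history: list = field(default_factory=list, repr=False)


def geomin_criterion(L: np.ndarray, epsilon: float, skip_first: bool = False):
    """Criterion value and gradient dQ/dL (penalized columns only)."""
    L2 = L**2 + epsilon
    cols = slice(1, None) if skip_first else slice(None)
    Lp = L2[:, cols]
    q = Lp.shape[1]
    logs = np.log(Lp)
    row = np.exp(logs.sum(axis=1) / q)
    f = row.sum()
    G = np.zeros_like(L)
    G[:, cols] = row[:, None] * (2.0 / q) * L[:, cols] / Lp
    return f, G


def _random_orthogonal(k: int, rng) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((k, k)))
    return q * np.sign(np.diag(r))


def _gpa_orth(A, vgQ, T0, max_iter=1000, tol=1e-7):
    T = T0.copy()
    al = 1.0
    L = A @ T
    f, Gq = vgQ(L)
    G = A.T @ Gq
    history = [f]
    for _ in range(max_iter):
        M = T.T @ G
        Sym = 0.5 * (M + M.T)
        Gp = G - T @ Sym
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            return L, T, f, True, history
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            U, _, Vt = np.linalg.svd(X)
            Tt = U @ Vt
            Lt = A @ Tt
            ft, Gqt = vgQ(Lt)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, L, f, Gq = Tt, Lt, ft, Gqt
        G = A.T @ Gq
        history.append(f)
    return L, T, f, False, history


def _gpa_oblique(A, vgQ, T0, max_iter=1000, tol=1e-7):
    T = T0.copy()
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = vgQ(L)
    G = -(L.T @ Gq @ Ti).T
    history = [f]
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            return L, T, f, True, history
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            nrm = np.sqrt((X**2).sum(axis=0))
            Tt = X / nrm
            Tit = np.linalg.inv(Tt)
            Lt = A @ Tit.T
            ft, Gqt = vgQ(Lt)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, L, f, Gq, Ti = Tt, Lt, ft, Gqt, Tit
        G = -(L.T @ Gq @ Ti).T
        history.append(f)
    return L, T, f, False, history


def _fix_signs(L, phi):
    """Largest-|loading| entry of each factor made positive."""
    L = L.copy()
    phi = phi.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] *= -1.0
            phi[j, :] *= -1.0
            phi[:, j] *= -1.0
    return L, phi


def _rotate(A, epsilon, n_starts, random_state, oblique, skip_first):
    A = np.asarray(A, dtype=float)
    p, k = A.shape
    if k < 2:
        raise ValueError("rotation requires at least 2 factors")
    rng = np.random.default_rng(random_state)

    def vgQ(L):
        return geomin_criterion(L, epsilon, skip_first=skip_first)

    driver = _gpa_oblique if oblique else _gpa_orth
    best = None
    any_conv = False
    for s in range(max(1, n_starts)):
        T0 = np.eye(k) if s == 0 else _random_orthogonal(k, rng)
        L, T, f, conv, hist = driver(A, vgQ, T0)
        any_conv = any_conv or conv
        if best is None or f < best[2] - 1e-12:
            best = (L, T, f, conv, hist)
    L, T, f, conv, hist = best
    phi = T.T @ T if oblique else np.eye(k)
    L, phi = _fix_signs(L, phi)
    if not any_conv:
        logger.warning("rotation did not converge in any of %d starts", n_starts)
    return RotationSolution(
        rotated_loadings=L,
        factor_correlations=phi,
        criterion_value=float(f),
        rotation_matrix=T,
        converged=any_conv,
        n_random_starts=max(1, n_starts),
        history=hist,
    )


def geomin_rotate(loadings, epsilon: float = 0.01, n_starts: int = 30,
                  random_state=None) -> RotationSolution:
    """Oblique geomin rotation, best of ``n_starts`` orthonormal starts."""
    return _rotate(loadings, epsilon, n_starts, random_state,
                   oblique=True, skip_first=False)


def bifactor_geomin_rotate(loadings, epsilon: float = 0.01, n_starts: int = 30,
                           random_state=None) -> RotationSolution:
    """Orthogonal bi-factor geomin rotation.

    Column 1 of the result is the general factor (unpenalized); the geomin
    criterion acts on the remaining columns. All factors are uncorrelated.
    """
    return _rotate(loadings, epsilon, n_starts, random_state,
                   oblique=False, skip_first=True)


# ----------------------------------------------------------------------
def match_factors(estimated: np.ndarray, target: np.ndarray):
    """Best column permutation/sign alignment of ``estimated`` to ``target``.

    Hungarian assignment on absolute Tucker congruence; returns the aligned
    loadings, the permutation and the signs.
    """
    est = np.asarray(estimated, float)
    tgt = np.asarray(target, float)
    norm_e = np.linalg.norm(est, axis=0)
    norm_t = np.linalg.norm(tgt, axis=0)
    cong = (est.T @ tgt) / np.outer(
        np.maximum(norm_e, 1e-12), np.maximum(norm_t, 1e-12)
    )
    rows, cols = linear_sum_assignment(-np.abs(cong))
    perm = np.empty(tgt.shape[1], dtype=int)
    signs = np.empty(tgt.shape[1])
    for r, c in zip(rows, cols):
        perm[c] = r
        signs[c] = np.sign(cong[r, c]) or 1.0
    aligned = est[:, perm] * signs
    return aligned, perm, signs


def simple_structure_from_rotation(solution: RotationSolution,
                                   rule: float = 0.1,
                                   pattern: np.ndarray | None = None,
                                   drop: tuple = ()) -> np.ndarray:
    """Free/fixed CFA pattern from a converged rotated solution.

    If ``pattern`` is supplied it is returned as-is (the packaged
    confirmatory simple structure is the default route in the pipeline);
    otherwise loadings with ``|λ| >= rule`` are retained with their signs
    and values. Columns listed in ``drop`` (e.g. a residual factor) are
    removed. A factor left with no indicators is an identification error.
    """
    if pattern is not None:
        pat = np.asarray(pattern, dtype=float)
    else:
        L = solution.rotated_loadings
        pat = np.where(np.abs(L) >= rule, L, 0.0)
    if drop:
        pat = np.delete(pat, list(drop), axis=1)
    empty = np.flatnonzero((pat != 0).sum(axis=0) == 0)
    if empty.size:
        raise ValueError(
            f"factor(s) {empty.tolist()} have no retained indicators; "
            "the CFA would be unidentified"
        )
    return pat
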