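"""Model-implied trio moment structure.

Coordinates are ordered mother (11), father (11), child (11). With Λ the
loading matrix, ψ the (diagonal) parental factor variances, γ the diagonal
mother-father factor covariances, ψ_w the fixed within-family variance and
Θ the diagonal residual variances, the child's latent factors are
F_c = ½F_m + ½F_f + S with Var(S) = ψ_w·I, giving

    Σ_mm = Σ_ff = Λ diag(ψ) Λᵀ + Θ
    Σ_mf = Λ diag(γ) Λᵀ
    Σ_mc = Σ_fc = Λ diag(½(ψ+γ)) Λᵀ [+ ½Θ if uniques are transmitted]
    Σ_cc = Λ diag(½(ψ+γ) + ψ_w) Λᵀ + Θ

and, when latent means are modelled (ν = 0, within mean 0),

    μ_m = Λα_m,  μ_f = Λα_f,  μ_c = ½Λ(α_m + α_f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spec import TrioModelSpec

_ROLE_OFFSET = {"mother": 0, "father": 1, "child": 2}


@dataclass
class MomentStructure:
    """Implied 33-dimensional mean vector and covariance of one trio."""

    mean: np.ndarray
    cov: np.ndarray
    trait_labels: tuple

    def index(self, role: str, trait: str) -> int:
        p = len(self.trait_labels)
        return _ROLE_OFFSET[role] * p + self.trait_labels.index(trait)

    def block(self, role_a: str, role_b: str) -> np.ndarray:
        p = len(self.trait_labels)
        i, j = _ROLE_OFFSET[role_a] * p, _ROLE_OFFSET[role_b] * p
        return self.cov[i:i + p, j:j + p]


def implied_moments(spec: TrioModelSpec, theta: np.ndarray) -> MomentStructure:
    """Implied trio moments at a raw-scale parameter vector."""
    b = spec.unpack(theta)
    lam, psi, gamma, resid = b["lam"], b["psi"], b["gamma"], b["theta"]
    p = spec.n_traits

    par = (lam * psi) @ lam.T + np.diag(resid)
    mf = (lam * gamma) @ lam.T
    half = 0.5 * (psi + gamma)
    pc = (lam * half) @ lam.T
    if spec.transmit_unique:
        pc = pc + np.diag(0.5 * resid)
    cc = (lam * (half + spec.psi_within)) @ lam.T + np.diag(resid)

    cov = np.empty((3 * p, 3 * p))
    cov[:p, :p] = par
    cov[p:2 * p, p:2 * p] = par
    cov[2 * p:, 2 * p:] = cc
    cov[:p, p:2 * p] = mf
    cov[p:2 * p, :p] = mf.T
    cov[:p, 2 * p:] = pc
    cov[2 * p:, :p] = pc.T
    cov[p:2 * p, 2 * p:] = pc
    cov[2 * p:, p:2 * p] = pc.T
    cov = 0.5 * (cov + cov.T)  # exact symmetry

    mean = np.zeros(3 * p)
    if spec.estimate_latent_means:
        mean[:p] = lam @ b["alpha_m"]
        mean[p:2 * p] = lam @ b["alpha_f"]
        mean[2 * p:] = lam @ (0.5 * (b["alpha_m"] + b["alpha_f"]))
    return MomentStructure(mean=mean, cov=cov, trait_labels=tuple(spec.trait_labels))
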