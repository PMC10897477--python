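"""Free/fixed parameter patterns for the trio bifactor model.

The measurement model is shared by mother, father and child (one loading
matrix, one set of residual variances — the sexes are tied by default).
Transmission paths from each parental factor to the child factor are fixed
at 0.5, reflecting meiosis, and the child's segregation (within-family)
factor variance is fixed by the spec — that fixed value is what identifies
the latent scale:

* baseline / selection-means model: within-family variance fixed at 0.5
  and within-family mean fixed at 0, so parental factor variances and
  latent means are expressed on the population scale;
* assortment model: within-family variance fixed at 1; the mother-father
  latent covariances are then standardized against the (free) parental
  variances to give partner correlations.

Observed variables are assumed pre-standardized polygenic scores: the
scaling constants δ are fixed at 1 and, when latent means are estimated,
the intercepts ν are fixed at 0 so that the population mean zero defined
by the standardization anchors the latent means. (With ν free the mean
structure is unidentified: a common latent shift on both parents can be
absorbed into ν without changing any implied mean.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import TRAITS


@dataclass
class TrioModelSpec:
    """Pattern of free/fixed parameters for the trio model.

    Parameters
    ----------
    pattern : (p, k) array
        Signed loading pattern: zero entries are fixed at 0; nonzero
        entries are free, their values serving as starting values (sign
        included, e.g. a negative alcohol-use loading on constraint).
    psi_within : float
        Fixed within-family (segregation) factor variance per factor.
    estimate_partner_cov : bool
        Free diagonal mother-father latent covariances Γ.
    estimate_latent_means : bool
        Free per-parent latent means α_m, α_f (structured mean model with
        ν = 0, δ = 1); otherwise the observed means are saturated.
    transmit_unique : bool
        Child unique components follow the ½/½/½Θ transmission rule
        (parent-child residual covariance ½Θ); otherwise independent.
    """

    pattern: np.ndarray
    psi_within: float = 0.5
    estimate_partner_cov: bool = False
    estimate_latent_means: bool = False
    transmit_unique: bool = True
    trait_labels: tuple = TRAITS
    factor_labels: tuple | None = None

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=float)
        if self.pattern.ndim != 2:
            raise ValueError("pattern must be 2-d")
        p, k = self.pattern.shape
        if p != len(self.trait_labels):
            raise ValueError("pattern rows must match trait_labels")
        if self.factor_labels is None:
            self.factor_labels = tuple(f"F{j + 1}" for j in range(k))
        if (np.abs(self.pattern).sum(axis=0) == 0).any():
            raise ValueError("every factor needs at least one free loading")
        self._free_idx = np.argwhere(self.pattern != 0)

    # ------------------------------------------------------------------
    @property
    def n_traits(self) -> int:
        return self.pattern.shape[0]

    @property
    def n_factors(self) -> int:
        return self.pattern.shape[1]

    @property
    def n_free_loadings(self) -> int:
        return len(self._free_idx)

    @property
    def n_params(self) -> int:
        p, k = self.pattern.shape
        n = self.n_free_loadings + k + p  # loadings + psi + theta
        if self.estimate_partner_cov:
            n += k
        if self.estimate_latent_means:
            n += 2 * k
        return n

    def param_names(self) -> list[str]:
        t, f = self.trait_labels, self.factor_labels
        names = [f"lambda[{t[i]},{f[j]}]" for i, j in self._free_idx]
        names += [f"psi[{x}]" for x in f]
        if self.estimate_partner_cov:
            names += [f"gamma[{x}]" for x in f]
        names += [f"theta[{x}]" for x in t]
        if self.estimate_latent_means:
            names += [f"alpha_m[{x}]" for x in f]
            names += [f"alpha_f[{x}]" for x in f]
        return names

    # ------------------------------------------------------------------
    def slices(self) -> dict:
        k, p = self.n_factors, self.n_traits
        out, pos = {}, 0
        for name, size in (
            ("lam", self.n_free_loadings),
            ("psi", k),
            ("gamma", k if self.estimate_partner_cov else 0),
            ("theta", p),
            ("alpha_m", k if self.estimate_latent_means else 0),
            ("alpha_f", k if self.estimate_latent_means else 0),
        ):
            out[name] = slice(pos, pos + size)
            pos += size
        return out

    def unpack(self, theta: np.ndarray) -> dict:
        """Raw parameter vector -> named blocks (full loading matrix)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"theta has length {theta.shape}, expected {self.n_params}"
            )
        sl = self.slices()
        k = self.n_factors
        lam = np.zeros_like(self.pattern)
        lam[self._free_idx[:, 0], self._free_idx[:, 1]] = theta[sl["lam"]]
        out = {
            "lam": lam,
            "psi": theta[sl["psi"]],
            "gamma": theta[sl["gamma"]] if self.estimate_partner_cov else np.zeros(k),
            "theta": theta[sl["theta"]],
            "alpha_m": theta[sl["alpha_m"]] if self.estimate_latent_means else np.zeros(k),
            "alpha_f": theta[sl["alpha_f"]] if self.estimate_latent_means else np.zeros(k),
        }
        return out

    def pack(self, lam, psi, gamma=None, theta=None, alpha_m=None, alpha_f=None):
        parts = [np.asarray(lam)[self._free_idx[:, 0], self._free_idx[:, 1]],
                 np.asarray(psi, dtype=float)]
        if self.estimate_partner_cov:
            parts.append(np.asarray(gamma, dtype=float))
        parts.append(np.asarray(theta, dtype=float))
        if self.estimate_latent_means:
            parts.append(np.asarray(alpha_m, dtype=float))
            parts.append(np.asarray(alpha_f, dtype=float))
        return np.concatenate(parts)

    # positive parameters (variances) live on the log scale during
    # optimization to avoid Heywood crashes
    def _pos_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_params, dtype=bool)
        sl = self.slices()
        mask[sl["psi"]] = True
        mask[sl["theta"]] = True
        return mask

    def to_optim(self, theta_raw: np.ndarray) -> np.ndarray:
        z = np.array(theta_raw, dtype=float)
        m = self._pos_mask()
        z[m] = np.log(np.maximum(z[m], 1e-8))
        return z

    def from_optim(self, z: np.ndarray) -> np.ndarray:
        theta = np.array(z, dtype=float)
        m = self._pos_mask()
        theta[m] = np.exp(np.clip(theta[m], -30, 30))
        return theta

    # ------------------------------------------------------------------
    def init_theta(self) -> np.ndarray:
        """Default starting values on the raw scale.

        The latent scale implied by ``psi_within`` is accounted for: with
        within-family variance fixed at c·0.5, loadings shrink by 1/√(2c)
        relative to a population-standardized pattern and parental
        variances start at 2c·0.5.
        """
        c = self.psi_within / 0.5
        base = self.pattern[self._free_idx[:, 0], self._free_idx[:, 1]]
        base = np.where(np.abs(base) == 1.0, 0.3 * np.sign(base), base)
        lam0 = base / np.sqrt(c)
        k, p = self.n_factors, self.n_traits
        lam_full = np.zeros_like(self.pattern)
        lam_full[self._free_idx[:, 0], self._free_idx[:, 1]] = base
        theta0 = np.clip(1.0 - (lam_full**2).sum(axis=1), 0.05, 1.0)
        parts = [lam0, np.full(k, c)]
        if self.estimate_partner_cov:
            parts.append(np.zeros(k))
        parts.append(theta0)
        if self.estimate_latent_means:
            parts.append(np.zeros(2 * k))
        return np.concatenate(parts)

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern.tolist(),
            "psi_within": self.psi_within,
            "estimate_partner_cov": self.estimate_partner_cov,
            "estimate_latent_means": self.estimate_latent_means,
            "transmit_unique": self.transmit_unique,
            "trait_labels": list(self.trait_labels),
            "factor_labels": list(self.factor_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrioModelSpec":
        d = dict(d)
        for key in ("trait_labels", "factor_labels"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ----------------------------------------------------------------------
def assortment_spec(pattern, trait_labels=TRAITS, factor_labels=None,
                    transmit_unique=True) -> TrioModelSpec:
    """Partner-correlation CFA: within-family variance fixed to 1, free
    mother-father latent covariances; saturated observed means."""
    return TrioModelSpec(
        pattern, psi_within=1.0, estimate_partner_cov=True,
        estimate_latent_means=False, transmit_unique=transmit_unique,
        trait_labels=trait_labels, factor_labels=factor_labels,
    )


def selection_means_spec(pattern, trait_labels=TRAITS, factor_labels=None,
                         estimate_partner_cov=True,
                         transmit_unique=True) -> TrioModelSpec:
    """Sex-specific selection model: within-family variance fixed to 0.5,
    within-family mean fixed to 0, free parental latent means (ν = 0)."""
    return TrioModelSpec(
        pattern, psi_within=0.5, estimate_partner_cov=estimate_partner_cov,
        estimate_latent_means=True, transmit_unique=transmit_unique,
        trait_labels=trait_labels, factor_labels=factor_labels,
    )


def baseline_spec(pattern, **kw) -> TrioModelSpec:
    """Baseline identification: within variance 0.5, within mean 0."""
    return selection_means_spec(pattern, **kw)
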