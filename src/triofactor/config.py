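"""Generative configuration for synthetic trio polygenic-score panels.

The generator draws mother/father latent genetic factor scores from a joint
Gaussian (allowing cross-partner covariance, i.e. assortative mating, and
sex-specific latent mean shifts, i.e. participation selection), transmits
them to a child under Mendelian segregation (midparent + segregation
deviation carrying half the population additive variance), and maps latents
to observed polygenic scores through a bifactor loading matrix.

Two calibrated parameter sets ship with the package:

* a five-factor exploratory loading matrix (general psychopathology factor,
  neurodevelopmental, psychotic-disorders and constraint subfactors, plus a
  depression residual factor) with per-trait residual variances, and
* the four-factor confirmatory simple structure derived from it (the
  residual factor dropped, only the salient loadings retained).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

#: Canonical ordering of the 11 psychiatric polygenic scores.
TRAITS: tuple[str, ...] = (
    "ADHD", "ANOR", "ASD", "BIPO", "MDD", "NEUR",
    "OCD", "PTSD", "SCHZ", "ANXI", "AUD",
)

#: Confirmatory bifactor factor labels (general factor first).
BIFACTOR_LABELS: tuple[str, ...] = ("p", "NDV", "PSYCH", "CONS")

ROLES: tuple[str, ...] = ("mother", "father", "child")


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("triofactor.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def efa_loadings_5factor(include_error: bool = False) -> pd.DataFrame:
    """Packaged five-factor exploratory loading matrix (calibrated defaults).

    Parameters
    ----------
    include_error : bool
        If True, keep the per-trait residual-variance column ``error``.
    """
    df = _read_packaged("efa_loadings_5factor.tsv")
    return df if include_error else df.drop(columns="error")


def cfa_simple_structure() -> pd.DataFrame:
    """Packaged four-factor confirmatory simple structure (signed loadings).

    Zero entries are fixed at zero in the CFA; nonzero entries are free,
    their values doubling as calibrated generating loadings and as starting
    values (note the negative alcohol-use loading on the constraint factor).
    """
    return _read_packaged("cfa_simple_structure.tsv")


@dataclass
class GenerativeConfig:
    """Full parameterization of the synthetic trio generator.

    Attributes
    ----------
    loadings : (11, k) array
        Factor loading matrix Λ; general factor in column 0 by convention.
    factor_cov : (k, k) array
        Population latent factor covariance Ψ (identity = orthogonal bifactor).
    partner_cross_cov : (k, k) array
        Cross-partner latent covariance Γ; Γ[j, j] is the per-factor
        assortment parameter.
    selection_means_mother, selection_means_father : (k,) arrays
        Latent mean shifts α of the participating parents relative to the
        population mean of zero (standardized-factor units).
    unique_var : (11,) array
        Trait-specific residual genetic variances (diagonal of Θ).
    n_trios : int
        Number of complete mother-father-child trios to generate.
    seed : int
        Seed for the random generator; full determinism given the seed.
    transmit_unique : bool
        If True (default) trait-specific genetic components follow the same
        midparent + segregation rule as the latent factors; if False the
        child's unique component is drawn independently with variance Θ.
    selection_mode : str
        ``"mean_shift"`` (default): parents are drawn directly with the
        shifted latent means. ``"threshold"``: parents are drawn from the
        unshifted population and retained by a probit participation model
        with per-factor liability weights given by the selection means and
        participation rate ``participation_rate`` (robustness mode).
    """

    loadings: np.ndarray
    factor_cov: np.ndarray | None = None
    partner_cross_cov: np.ndarray | None = None
    selection_means_mother: np.ndarray | None = None
    selection_means_father: np.ndarray | None = None
    unique_var: np.ndarray | None = None
    n_trios: int = 25_293
    seed: int = 0
    trait_labels: tuple[str, ...] = TRAITS
    factor_labels: tuple[str, ...] | None = None
    transmit_unique: bool = True
    selection_mode: str = "mean_shift"
    participation_rate: float = 0.41

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 2:
            raise ValueError("loadings must be a 2-d array")
        p, k = self.loadings.shape
        if p != len(self.trait_labels):
            raise ValueError(
                f"loadings has {p} rows but {len(self.trait_labels)} trait labels"
            )
        if self.factor_cov is None:
            self.factor_cov = np.eye(k)
        if self.partner_cross_cov is None:
            self.partner_cross_cov = np.zeros((k, k))
        if self.selection_means_mother is None:
            self.selection_means_mother = np.zeros(k)
        if self.selection_means_father is None:
            self.selection_means_father = np.zeros(k)
        if self.unique_var is None:
            # default: unit total variance per trait under Ψ
            common = np.einsum(
                "ij,jl,il->i", self.loadings, self.factor_cov, self.loadings
            )
            self.unique_var = 1.0 - common
        for name in ("factor_cov", "partner_cross_cov"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("selection_means_mother", "selection_means_father", "unique_var"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if self.factor_labels is None:
            self.factor_labels = tuple(f"F{j + 1}" for j in range(k))
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_traits(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def joint_couple_cov(self) -> np.ndarray:
        """2k x 2k covariance of the stacked (mother, father) latent factors."""
        psi, gamma = self.factor_cov, self.partner_cross_cov
        return np.block([[psi, gamma], [gamma.T, psi]])

    def population_cov(self) -> np.ndarray:
        """Model-implied 11 x 11 population covariance Λ Ψ Λᵀ + Θ."""
        lam = self.loadings
        return lam @ self.factor_cov @ lam.T + np.diag(self.unique_var)

    def validate(self) -> None:
        k = self.n_factors
        psi = self.factor_cov
        if psi.shape != (k, k):
            raise ValueError(f"factor_cov must be {k}x{k}, got {psi.shape}")
        if not np.allclose(psi, psi.T, atol=1e-10):
            raise ValueError("factor_cov is not symmetric")
        if np.linalg.eigvalsh(psi).min() < -1e-10:
            raise ValueError("factor_cov is not positive semi-definite")
        if self.partner_cross_cov.shape != (k, k):
            raise ValueError("partner_cross_cov has wrong shape")
        joint = self.joint_couple_cov()
        if np.linalg.eigvalsh(joint).min() < -1e-10:
            raise ValueError(
                "joint couple covariance [[Psi, Gamma], [Gamma.T, Psi]] is not "
                "positive semi-definite; check partner_cross_cov"
            )
        if (self.unique_var < 0).any():
            bad = [
                t for t, v in zip(self.trait_labels, self.unique_var) if v < 0
            ]
            raise ValueError(f"negative unique variance for traits {bad}")
        for name in ("selection_means_mother", "selection_means_father"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} must have length {k}")
        if self.n_trios <= 0:
            raise ValueError("n_trios must be positive")
        if self.selection_mode not in ("mean_shift", "threshold"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeConfig":
        d = dict(d)
        for key in ("trait_labels", "factor_labels"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenerativeConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(
    n_trios: int = 25_293,
    seed: int = 0,
    five_factor: bool = False,
    **overrides,
) -> GenerativeConfig:
    """Calibrated generating configuration.

    ``five_factor=False`` (default) uses the four-factor confirmatory simple
    structure with unique variances set to 1 - Σλ² so every trait has unit
    population variance. ``five_factor=True`` uses the full five-factor
    exploratory matrix with its tabulated residual variances.
    """
    if five_factor:
        df = efa_loadings_5factor(include_error=True)
        lam = df.drop(columns="error").to_numpy()
        theta = df["error"].to_numpy()
        labels = tuple(df.columns.drop("error"))
    else:
        df = cfa_simple_structure()
        lam = df.to_numpy()
        theta = 1.0 - (lam**2).sum(axis=1)
        labels = tuple(df.columns)
    cfg = dict(
        loadings=lam,
        unique_var=theta,
        n_trios=n_trios,
        seed=seed,
        trait_labels=tuple(df.index),
        factor_labels=labels,
    )
    cfg.update(overrides)
    return GenerativeConfig(**cfg)
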