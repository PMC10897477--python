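"""Synthetic trio generator: assortative couples, Mendelian transmission,
participation selection, and the latent-to-observed polygenic-score map.

The generative model, per family:

* (F_m, F_f) ~ N((α_m, α_f), [[Ψ, Γ], [Γᵀ, Ψ]]) — mother/father latent
  genetic factors with population covariance Ψ each, cross-partner
  covariance Γ (assortative mating) and sex-specific mean shifts α
  (participation selection).
* U_m, U_f ~ N(0, Θ) — trait-specific genetic components, independent
  across partners (assortment acts on the latent factors).
* Meiosis: F_c = ½F_m + ½F_f + S with S ~ N(0, ½Ψ), and by default the
  unique components follow the same rule, U_c = ½U_m + ½U_f + W with
  W ~ N(0, ½Θ); segregation deviations carry half the population additive
  variance, so Var(child) = Var(parent) under random mating.
* Observed scores: Y = ΛF + U per person.

Selection shifts parental (and hence child) means but never touches the
child-minus-midparent deviation, whose mean stays at zero — the property
that makes the within-family design immune to participation bias.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .config import GenerativeConfig
from .datasets import TrioDataset

__all__ = [
    "simulate_couples",
    "transmit",
    "emit_pgs",
    "simulate_trios",
    "standardize_panel",
    "TrioSimulator",
]


def _rng(config: GenerativeConfig, rng=None) -> np.random.Generator:
    return np.random.default_rng(config.seed) if rng is None else rng


def simulate_couples(config: GenerativeConfig, rng=None) -> np.ndarray:
    """Draw couple latent factors, (n_trios, 2k): mother columns first.

    Under ``selection_mode="mean_shift"`` the joint Gaussian has means
    (α_m, α_f) directly. Under ``"threshold"`` couples are drawn from the
    unshifted population and retained when both partners pass a probit
    participation model whose per-factor liability weights are the
    selection means (robustness mode; the realized mean shift then depends
    on the weights and the participation rate).
    """
    k = config.n_factors
    joint = config.joint_couple_cov()
    # explicit PSD check with a block-aware message
    if np.linalg.eigvalsh(config.factor_cov).min() < -1e-10:
        raise ValueError("factor_cov block is not positive semi-definite")
    if np.linalg.eigvalsh(joint).min() < -1e-10:
        raise ValueError(
            "partner_cross_cov makes the joint couple covariance "
            "[[Psi, Gamma], [Gamma.T, Psi]] non-PSD"
        )
    rng = _rng(config, rng)
    chol = np.linalg.cholesky(joint + 1e-12 * np.eye(2 * k))
    if config.selection_mode == "mean_shift":
        mean = np.concatenate(
            [config.selection_means_mother, config.selection_means_father]
        )
        z = rng.standard_normal((config.n_trios, 2 * k))
        return mean + z @ chol.T
    # threshold participation: oversample and keep couples where both
    # partners participate.
    w_m, w_f = config.selection_means_mother, config.selection_means_father
    cut = stats.norm.ppf(1.0 - config.participation_rate)
    kept = []
    n_kept = 0
    while n_kept < config.n_trios:
        m = max(2 * config.n_trios, 1000)
        z = rng.standard_normal((m, 2 * k)) @ chol.T
        liab_m = z[:, :k] @ w_m + rng.standard_normal(m)
        liab_f = z[:, k:] @ w_f + rng.standard_normal(m)
        sel = (liab_m > cut) & (liab_f > cut)
        kept.append(z[sel])
        n_kept += sel.sum()
    return np.vstack(kept)[: config.n_trios]


def draw_unique_components(config: GenerativeConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Independent parental trait-specific components, each (n, 11)."""
    sd = np.sqrt(config.unique_var)
    n = config.n_trios
    return (
        rng.standard_normal((n, config.n_traits)) * sd,
        rng.standard_normal((n, config.n_traits)) * sd,
    )


def transmit(
    mother_factors,
    mother_uniques,
    father_factors,
    father_uniques,
    config: GenerativeConfig,
    rng=None,
    segregation_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mendelian transmission: child = midparent + segregation deviation.

    ``segregation_scale`` multiplies the segregation standard deviation;
    0 gives the exact-midparent degenerate limit (useful in tests).
    """
    mother_factors = np.asarray(mother_factors, dtype=float)
    father_factors = np.asarray(father_factors, dtype=float)
    if mother_factors.shape != father_factors.shape:
        raise ValueError("mother and father factor blocks differ in shape")
    if mother_uniques is not None and (
        np.shape(mother_uniques) != np.shape(father_uniques)
    ):
        raise ValueError("mother and father unique blocks differ in shape")
    rng = _rng(config, rng)
    n, k = mother_factors.shape
    if k != config.n_factors:
        raise ValueError(
            f"factor blocks have {k} columns, config expects {config.n_factors}"
        )
    seg_chol = np.linalg.cholesky(
        0.5 * config.factor_cov + 1e-12 * np.eye(k)
    )
    s = segregation_scale * (rng.standard_normal((n, k)) @ seg_chol.T)
    child_factors = 0.5 * (mother_factors + father_factors) + s

    if config.transmit_unique and mother_uniques is not None:
        w_sd = segregation_scale * np.sqrt(0.5 * config.unique_var)
        w = rng.standard_normal((n, config.n_traits)) * w_sd
        child_uniques = 0.5 * (mother_uniques + father_uniques) + w
    else:
        sd = segregation_scale * np.sqrt(config.unique_var)
        child_uniques = rng.standard_normal((n, config.n_traits)) * sd
    return child_factors, child_uniques


def emit_pgs(latents: dict, config: GenerativeConfig) -> TrioDataset:
    """Map latent draws to observed polygenic scores, Y = ΛF + U per person.

    ``latents`` maps each role to a dict with ``factors`` (n, k) and
    ``uniques`` (n, 11). The generating latents are retained on the
    returned dataset as a synthetic-only truth block.
    """
    lam = config.loadings
    scores = {}
    for role in ("mother", "father", "child"):
        block = latents[role]
        scores[role] = block["factors"] @ lam.T + block["uniques"]
    return TrioDataset(
        scores, trait_labels=config.trait_labels, latent_truth=latents
    )


def simulate_trios(config: GenerativeConfig, rng=None) -> TrioDataset:
    """Full generator: couples -> uniques -> transmission -> observed scores."""
    rng = _rng(config, rng)
    couples = simulate_couples(config, rng)
    k = config.n_factors
    fm, ff = couples[:, :k], couples[:, k:]
    um, uf = draw_unique_components(config, rng)
    fc, uc = transmit(fm, um, ff, uf, config, rng)
    latents = {
        "mother": {"factors": fm, "uniques": um},
        "father": {"factors": ff, "uniques": uf},
        "child": {"factors": fc, "uniques": uc},
    }
    return emit_pgs(latents, config)


def standardize_panel(
    dataset: TrioDataset,
    covariates: dict | None = None,
    reference: str = "parents",
) -> TrioDataset:
    """Residualize each trait on covariates, then scale to mean 0, SD 1.

    Mirrors the usual polygenic-score post-processing (adjustment for
    genetic principal components and genotyping batch, then
    standardization). With no covariates this is plain z-scoring.

    Parameters
    ----------
    covariates : dict role -> (n, q) array, optional
        Covariate columns aligned with persons; residualization pools all
        persons in one OLS per trait.
    reference : {"parents", "all"}
        Group whose mean/SD define the standardization; applied to everyone.
    """
    roles = ("mother", "father", "child")
    blocks = [np.array(dataset.scores[r], dtype=float) for r in roles]
    n = dataset.n_trios
    if covariates is not None:
        X = np.vstack([np.asarray(covariates[r], dtype=float) for r in roles])
        X = np.column_stack([np.ones(len(X)), X])
        Y = np.vstack(blocks)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        blocks = [resid[i * n:(i + 1) * n] for i in range(3)]
    if reference == "parents":
        ref = np.vstack(blocks[:2])
    elif reference == "all":
        ref = np.vstack(blocks)
    else:
        raise ValueError("reference must be 'parents' or 'all'")
    mu, sd = ref.mean(axis=0), ref.std(axis=0)
    zero = np.flatnonzero(sd < 1e-12)
    if zero.size:
        bad = [dataset.trait_labels[i] for i in zero]
        raise ValueError(f"zero-variance trait column(s) after adjustment: {bad}")
    scores = {r: (b - mu) / sd for r, b in zip(roles, blocks)}
    return TrioDataset(scores, dataset.trait_labels, dataset.family_ids,
                       latent_truth=dataset.latent_truth)


class TrioSimulator:
    """Convenience sampler wrapping :func:`simulate_trios`.

    Not an estimator: it generates data from a known truth rather than
    fitting anything.
    """

    def __init__(self, config: GenerativeConfig):
        self.config = config

    def sample(self, seed: int | None = None) -> TrioDataset:
        rng = np.random.default_rng(
            self.config.seed if seed is None else seed
        )
        return simulate_trios(self.config, rng)
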