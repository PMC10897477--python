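"""End-to-end comorbidity analysis: descriptive partner correlations,
sequential between/within exploratory search with BIC selection, bi-factor
rotation, and confirmatory assortment / selection-mean models."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import BIFACTOR_LABELS, cfa_simple_structure
from .datasets import TrioDataset
from .efa import TwoLevelEFAResult, fit_two_level_efa
from .rotation import RotationSolution, bifactor_geomin_rotate
from .sem import FitResult, assortment_spec, fit_ml, selection_means_spec

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
def partner_pgs_correlations(data: TrioDataset, level: float = 0.95) -> pd.DataFrame:
    """Mother-father Pearson correlation per polygenic score, Fisher-z CI."""
    n = data.n_trios
    if n < 4:
        raise ValueError("need at least 4 trios for a Fisher-z interval")
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for t, trait in enumerate(data.trait_labels):
        r = float(np.corrcoef(data.scores["mother"][:, t],
                              data.scores["father"][:, t])[0, 1])
        zr = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        hw = z / np.sqrt(n - 3)
        rows.append((trait, r, float(np.tanh(zr - hw)), float(np.tanh(zr + hw))))
    return pd.DataFrame(rows, columns=["trait", "r", "ci_low", "ci_high"])


# ----------------------------------------------------------------------
@dataclass
class ModelSearchLedger:
    """BIC ledger of the sequential between/within factor search."""

    table: pd.DataFrame  # model, k_between, k_within, equal, loglik, n_params, bic, converged
    fits: list = field(repr=False, default_factory=list)

    @property
    def best_index(self) -> int:
        ok = self.table[self.table["converged"]]
        if ok.empty:
            raise RuntimeError("no converged model in the search")
        return int(ok["bic"].idxmin())

    @property
    def best(self) -> TwoLevelEFAResult:
        return self.fits[self.best_index]

    def to_dict(self) -> dict:
        return {"table": self.table.to_dict(orient="records"),
                "best_index": self.best_index}


def between_within_covariances(data: TrioDataset):
    """(S_between, n_between, S_within, n_within).

    Between: pooled parental covariance (2n person-level observations).
    Within: covariance of child-minus-midparent deviations, rescaled by 2
    to the population metric (segregation carries half the additive
    variance, matching the fixed 0.5 within-family variance of the trio
    model).
    """
    n = data.n_trios
    parents = np.vstack([data.scores["mother"], data.scores["father"]])
    parents = parents - parents.mean(axis=0)
    S_b = parents.T @ parents / (2 * n)
    dev = data.within_deviations()
    dev = dev - dev.mean(axis=0)
    S_w = 2.0 * (dev.T @ dev) / n
    return S_b, 2 * n, S_w, n


def sequential_efa_search(data: TrioDataset, max_k: int = 6) -> ModelSearchLedger:
    """Stepwise dimensionality/equality search over the two family levels.

    For each step k the ladder adds one factor between families, then one
    within families, then constrains the two structures to be equal
    (metric invariance), recording BIC (N = total person-level
    observations) at every rung; the converged model with minimum BIC is
    flagged best.
    """
    if max_k > 10:
        raise ValueError("max_k must be <= 10")
    S_b, n_b, S_w, n_w = between_within_covariances(data)
    N = n_b + n_w
    models: list[tuple[int, int, bool]] = [(0, 0, False)]
    for k in range(1, max_k + 1):
        models += [(k, k - 1, False), (k, k, False), (k, k, True)]
    rows, fits = [], []
    for i, (kb, kw, eq) in enumerate(models, start=1):
        try:
            res = fit_two_level_efa(S_b, n_b, S_w, n_w, kb, kw, equal_loadings=eq)
            bic = res.n_params * np.log(N) - 2.0 * res.loglik
            conv = res.converged
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("EFA step (%d,%d,eq=%s) failed: %s", kb, kw, eq, exc)
            res, bic, conv = None, np.inf, False
        if not conv:
            logger.warning("EFA step (%d,%d,eq=%s) did not converge; "
                           "excluded from selection", kb, kw, eq)
        rows.append((i, kb, kw, eq,
                     np.nan if res is None else res.loglik,
                     np.nan if res is None else res.n_params,
                     bic, conv))
        fits.append(res)
    table = pd.DataFrame(
        rows, columns=["model", "k_between", "k_within", "equal_structure",
                       "loglik", "n_params", "bic", "converged"],
    )
    return ModelSearchLedger(table=table, fits=fits)


def rotate_best_model(ledger: ModelSearchLedger, epsilon: float = 0.01,
                      n_starts: int = 30, random_state=None) -> RotationSolution:
    """Bi-factor geomin rotation of the best model's (between) loadings."""
    best = ledger.best
    return bifactor_geomin_rotate(best.loadings_between, epsilon=epsilon,
                                  n_starts=n_starts, random_state=random_state)


# ----------------------------------------------------------------------
def _pattern_and_labels(pattern):
    if pattern is None:
        df = cfa_simple_structure()
        return df.to_numpy(), tuple(df.columns), tuple(df.index)
    if isinstance(pattern, pd.DataFrame):
        return pattern.to_numpy(), tuple(pattern.columns), tuple(pattern.index)
    pat = np.asarray(pattern, dtype=float)
    return pat, tuple(f"F{j + 1}" for j in range(pat.shape[1])), None


def fit_cfa_assortment(data, pattern=None, n_starts: int = 10, seed: int = 0,
                       compute_se: bool = True, **fit_kw):
    """Partner-correlation CFA (within-family variance fixed to 1).

    Returns ``(FitResult, table)`` where the table reports, per factor, the
    standardized mother-father latent correlation b = γ/ψ with a Wald 95%
    CI obtained by the delta method.
    """
    pat, factors, traits = _pattern_and_labels(pattern)
    kw = {} if traits is None else {"trait_labels": traits}
    spec = assortment_spec(pat, factor_labels=factors, **kw)
    fr = fit_ml(spec, data, n_starts=n_starts, seed=seed,
                compute_se=compute_se, **fit_kw)
    sl = spec.slices()
    psi, gamma = fr.theta[sl["psi"]], fr.theta[sl["gamma"]]
    b = gamma / psi
    se_b = np.full_like(b, np.nan)
    if fr.cov_params is not None:
        for j in range(spec.n_factors):
            ig, ip = sl["gamma"].start + j, sl["psi"].start + j
            grad = np.zeros(spec.n_params)
            grad[ig] = 1.0 / psi[j]
            grad[ip] = -gamma[j] / psi[j] ** 2
            var_b = grad @ fr.cov_params @ grad
            # pseudo-inverse covariances can produce tiny negative forms
            se_b[j] = np.sqrt(var_b) if var_b > 0 else np.nan
    z = stats.norm.ppf(0.975)
    table = pd.DataFrame({
        "factor": list(factors),
        "b": b,
        "se": se_b,
        "ci_low": b - z * se_b,
        "ci_high": b + z * se_b,
    })
    return fr, table


def fit_cfa_selection_means(data, pattern=None, n_starts: int = 10,
                            seed: int = 0, compute_se: bool = True,
                            estimate_partner_cov: bool = True, **fit_kw):
    """Sex-specific selection CFA (within-family mean fixed to 0).

    Latent parental means are identified against the population zero
    defined by the standardization of the scores: the input data must be
    on the population-standardized scale and must NOT be re-centered (in
    particular not per sex), or the selection signal is destroyed.
    """
    pat, factors, traits = _pattern_and_labels(pattern)
    kw = {} if traits is None else {"trait_labels": traits}
    spec = selection_means_spec(pat, factor_labels=factors,
                                estimate_partner_cov=estimate_partner_cov, **kw)
    fr = fit_ml(spec, data, n_starts=n_starts, seed=seed,
                compute_se=compute_se, **fit_kw)
    sl = spec.slices()
    am, af = fr.theta[sl["alpha_m"]], fr.theta[sl["alpha_f"]]
    z = stats.norm.ppf(0.975)
    if fr.se is not None:
        se_m, se_f = fr.se[sl["alpha_m"]], fr.se[sl["alpha_f"]]
    else:
        se_m = se_f = np.full(spec.n_factors, np.nan)
    table = pd.DataFrame({
        "factor": list(factors),
        "alpha_mother": am, "se_mother": se_m,
        "ci_low_mother": am - z * se_m, "ci_high_mother": am + z * se_m,
        "alpha_father": af, "se_father": se_f,
        "ci_low_father": af - z * se_f, "ci_high_father": af + z * se_f,
    })
    return fr, table


# ----------------------------------------------------------------------
@dataclass
class AnalysisReport:
    """Serializable aggregate of all pipeline stages."""

    partner_pgs: pd.DataFrame | None = None
    ledger: dict | None = None
    rotated_loadings: pd.DataFrame | None = None
    assortment: pd.DataFrame | None = None
    selection_means: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    _FRAMES = ("partner_pgs", "rotated_loadings", "assortment", "selection_means")

    def gaps(self) -> list[str]:
        return [f for f in (*self._FRAMES, "ledger")
                if getattr(self, f) is None]

    def to_dict(self) -> dict:
        out = {"provenance": self.provenance, "ledger": self.ledger,
               "missing_stages": self.gaps()}
        for f in self._FRAMES:
            df = getattr(self, f)
            out[f] = None if df is None else df.to_dict(orient="split")
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        kw = {"provenance": d.get("provenance", {}), "ledger": d.get("ledger")}
        for f in cls._FRAMES:
            v = d.get(f)
            kw[f] = None if v is None else pd.DataFrame(
                v["data"], columns=v["columns"], index=v["index"])
        return cls(**kw)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "AnalysisReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_markdown(self) -> str:
        parts = ["# Trio polygenic-score comorbidity report", ""]
        if self.provenance:
            parts += ["## Provenance",
                      "", "```", json.dumps(self.provenance, indent=2), "```", ""]
        for title, f in (("Partner polygenic-score correlations", "partner_pgs"),
                         ("Bi-factor rotated loadings", "rotated_loadings"),
                         ("Partner latent correlations (assortment CFA)", "assortment"),
                         ("Parental latent means (selection CFA)", "selection_means")):
            df = getattr(self, f)
            if df is not None:
                parts += [f"## {title}", "", df.round(4).to_markdown(), ""]
        if self.ledger is not None:
            parts += ["## Model search ledger", "",
                      pd.DataFrame(self.ledger["table"]).round(2).to_markdown(), ""]
        missing = self.gaps()
        if missing:
            parts += ["## Missing stages", "", ", ".join(missing), ""]
        return "\n".join(parts)


def provenance_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]


def build_report(partner_pgs=None, ledger=None, rotation=None,
                 assortment=None, selection_means=None,
                 config=None, seed=None,
                 trait_labels=None, factor_labels=None) -> AnalysisReport:
    """Assemble stage outputs into one serializable report.

    Missing stages are allowed and reported as explicit gaps.
    """
    from . import __version__
    rot = None
    if rotation is not None:
        L = rotation.rotated_loadings
        cols = [f"F{j + 1}" for j in range(L.shape[1])]
        rot = pd.DataFrame(L, columns=cols,
                           index=list(trait_labels) if trait_labels else None)
    prov = {"version": __version__}
    if seed is not None:
        prov["seed"] = seed
    if config is not None:
        cfg_dict = config.to_dict() if hasattr(config, "to_dict") else dict(config)
        prov["config_hash"] = provenance_hash(cfg_dict)
    return AnalysisReport(
        partner_pgs=partner_pgs,
        ledger=None if ledger is None else ledger.to_dict(),
        rotated_loadings=rot,
        assortment=assortment,
        selection_means=selection_means,
        provenance=prov,
    )
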