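"""Containers and I/O for complete mother-father-child polygenic-score panels."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ROLES, TRAITS

#: Suffix used per role in the wide (33-column) layout.
ROLE_SUFFIX = {"mother": "m", "father": "f", "child": "c"}


class TrioDataset:
    """Polygenic scores for complete parent-offspring trios.

    Parameters
    ----------
    scores : mapping role -> (n, p) array
        One row per family, one column per trait, for each of
        ``mother``, ``father`` and ``child``. Complete cases only: any
        missing value is rejected (the analyses are complete-trio analyses).
    trait_labels : sequence of str
        Trait names in column order; identical across roles.
    family_ids : sequence of str, optional
        Defaults to ``fam000001`` style identifiers.
    latent_truth : dict, optional
        Side block of generating latent values (factor scores and unique
        components per person). Only present for synthetic data; never used
        by the fitting code.
    """

    def __init__(self, scores, trait_labels=TRAITS, family_ids=None,
                 latent_truth=None):
        self.trait_labels = tuple(trait_labels)
        p = len(self.trait_labels)
        self.scores = {}
        n = None
        for role in ROLES:
            if role not in scores:
                raise ValueError(f"missing scores for role {role!r}")
            arr = np.asarray(scores[role], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != p:
                raise ValueError(
                    f"scores[{role!r}] must be (n, {p}), got {arr.shape}"
                )
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("roles have differing numbers of families")
            if not np.isfinite(arr).all():
                raise ValueError(
                    f"non-finite values in {role} scores; complete trios only"
                )
            self.scores[role] = arr
        if family_ids is None:
            family_ids = [f"fam{i + 1:06d}" for i in range(n)]
        if len(family_ids) != n:
            raise ValueError("family_ids length mismatch")
        self.family_ids = list(family_ids)
        self.latent_truth = latent_truth

    # ------------------------------------------------------------------
    @property
    def n_trios(self) -> int:
        return self.scores["mother"].shape[0]

    @property
    def n_traits(self) -> int:
        return len(self.trait_labels)

    def wide_array(self) -> np.ndarray:
        """(n, 3p) array in block order mother, father, child."""
        return np.hstack([self.scores[r] for r in ROLES])

    def wide(self) -> pd.DataFrame:
        cols = [
            f"{t}_{ROLE_SUFFIX[r]}" for r in ROLES for t in self.trait_labels
        ]
        return pd.DataFrame(self.wide_array(), columns=cols,
                            index=pd.Index(self.family_ids, name="family_id"))

    def long(self) -> pd.DataFrame:
        frames = []
        for role in ROLES:
            df = pd.DataFrame(self.scores[role], columns=list(self.trait_labels))
            df.insert(0, "role", role)
            df.insert(0, "family_id", self.family_ids)
            frames.append(df)
        return (
            pd.concat(frames, ignore_index=True)
            .sort_values(["family_id", "role"], kind="stable")
            .reset_index(drop=True)
        )

    def midparent(self) -> np.ndarray:
        return 0.5 * (self.scores["mother"] + self.scores["father"])

    def within_deviations(self) -> np.ndarray:
        """Child-minus-midparent deviations (the within-family layer)."""
        return self.scores["child"] - self.midparent()

    # ------------------------------------------------------------------
    def to_tsv(self, path, layout: str = "long") -> None:
        if layout == "long":
            self.long().to_csv(path, sep="\t", index=False)
        elif layout == "wide":
            self.wide().to_csv(path, sep="\t")
        else:
            raise ValueError("layout must be 'long' or 'wide'")

    @classmethod
    def from_tsv(cls, path, trait_labels=None) -> "TrioDataset":
        df = pd.read_csv(path, sep="\t")
        if "role" in df.columns:  # long layout
            if trait_labels is None:
                trait_labels = [
                    c for c in df.columns if c not in ("family_id", "role")
                ]
            pivots, fam_ids = {}, None
            for role in ROLES:
                sub = df[df["role"] == role].sort_values("family_id")
                if fam_ids is None:
                    fam_ids = sub["family_id"].tolist()
                elif sub["family_id"].tolist() != fam_ids:
                    raise ValueError("family_ids differ across roles")
                pivots[role] = sub[list(trait_labels)].to_numpy()
            return cls(pivots, trait_labels, fam_ids)
        # wide layout
        fam_col = "family_id" if "family_id" in df.columns else df.columns[0]
        fam_ids = df[fam_col].tolist()
        if trait_labels is None:
            trait_labels = [
                c[:-2] for c in df.columns if c.endswith("_m")
            ]
        scores = {
            role: df[[f"{t}_{sfx}" for t in trait_labels]].to_numpy()
            for role, sfx in ROLE_SUFFIX.items()
        }
        return cls(scores, trait_labels, fam_ids)

    def __repr__(self) -> str:
        return (
            f"TrioDataset(n_trios={self.n_trios}, n_traits={self.n_traits}, "
            f"latent_truth={'yes' if self.latent_truth else 'no'})"
        )
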