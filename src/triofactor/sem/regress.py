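"""Within-family residualization: child scores regressed on parental scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class WithinRegression:
    """Per-trait OLS of child polygenic score on mother + father scores."""

    residuals: pd.DataFrame  # n_trios x n_traits
    coefficients: pd.DataFrame  # rows: intercept, mother, father


def residualize_child_on_parents(data) -> WithinRegression:
    """Remove parental genetic effects from child scores by OLS.

    Under Mendelian transmission the expected coefficients are (0.5, 0.5)
    and the residuals carry the randomly segregated within-family
    variation, uncorrelated with anything transmitted from the parents.
    """
    traits = list(data.trait_labels)
    n = data.n_trios
    resid = np.empty((n, len(traits)))
    coefs = np.empty((3, len(traits)))
    ones = np.ones(n)
    for t, trait in enumerate(traits):
        m = data.scores["mother"][:, t]
        f = data.scores["father"][:, t]
        X = np.column_stack([ones, m, f])
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError(
                f"collinear parental scores for trait {trait!r}; "
                "cannot residualize"
            )
        y = data.scores["child"][:, t]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        coefs[:, t] = beta
        resid[:, t] = y - X @ beta
    return WithinRegression(
        residuals=pd.DataFrame(resid, columns=traits, index=data.family_ids),
        coefficients=pd.DataFrame(
            coefs, index=["intercept", "mother", "father"], columns=traits
        ),
    )
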