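"""Environment-trait preparation: inverse-normal transform and residualization.

Continuous traits are rank-based inverse-normal transformed (Blom offset by
default) and then residualized on age, age^2 and sex; age itself is
residualized only on sex.  Dichotomous traits pass through untouched with
0/1 coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EnvironmentTrait", "inverse_normal_transform", "residualize_trait", "prepare_traits"]


@dataclass
class EnvironmentTrait:
    """A named environment vector with its declared kind."""

    name: str
    kind: str  # "continuous" | "dichotomous"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "dichotomous"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        nonmiss = v[~np.isnan(v)]
        if np.unique(nonmiss).size < 2:
            raise ValueError(f"trait {self.name!r} needs >= 2 distinct non-missing values")
        if self.kind == "dichotomous" and not np.isin(nonmiss, [0.0, 1.0]).all():
            raise ValueError(f"dichotomous trait {self.name!r} must be coded 0/1")
        self.values = v


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with a configurable rank offset.

    Non-missing entries are replaced by standard-normal quantiles of
    ``(rank - offset) / (m + 1 - 2*offset)`` over the ``m`` non-missing
    values; ties receive their average rank; NaN stays NaN.  The default
    offset 3/8 gives Blom quantiles ``(r - 3/8) / (m + 1/4)``.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    obs = ~np.isnan(v)
    x = v[obs]
    m = x.size
    if np.unique(x).size < 2:
        raise ValueError("inverse-normal transform undefined for constant input")
    ranks = stats.rankdata(x, method="average")
    out[obs] = stats.norm.ppf((ranks - offset) / (m + 1.0 - 2.0 * offset))
    return out


def residualize_trait(trait, age=None, sex=None, *, is_age: bool = False) -> np.ndarray:
    """Least-squares residuals of a trait on intercept + age + age^2 + sex.

    When the trait *is* age (``is_age=True``) only intercept + sex are used.
    Missing trait entries stay missing; covariates must be non-missing
    wherever the trait is observed.  Raises on a collinear design.
    """
    y = np.asarray(trait, dtype=float)
    obs = ~np.isnan(y)
    cols = [np.ones(obs.sum())]
    if not is_age:
        if age is None:
            raise ValueError("age covariate required")
        a = np.asarray(age, dtype=float)[obs]
        if np.isnan(a).any():
            raise ValueError("age missing where trait observed")
        cols += [a, a**2]
    if sex is None:
        raise ValueError("sex covariate required")
    s = np.asarray(sex, dtype=float)[obs]
    if np.isnan(s).any():
        raise ValueError("sex missing where trait observed")
    cols.append(s)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariate design in residualization")
    beta, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
    out = np.full(y.shape, np.nan)
    out[obs] = y[obs] - X @ beta
    return out


def prepare_traits(
    table: pd.DataFrame,
    kinds: dict,
    age_col: str = "age",
    sex_col: str = "sex",
    offset: float = 3.0 / 8.0,
) -> pd.DataFrame:
    """Process a samples x traits table into model-ready environment vectors.

    Continuous traits are inverse-normal transformed then residualized on
    age, age^2 and sex (age only on sex); dichotomous traits pass through.
    ``kinds`` maps trait name -> "continuous" | "dichotomous".  The age and
    sex columns are consumed as covariates and, when themselves declared as
    traits, processed under their special-case rules (sex passes through as
    a dichotomous trait).
    """
    out = pd.DataFrame(index=table.index)
    age = table[age_col].to_numpy(dtype=float) if age_col in table else None
    sex = table[sex_col].to_numpy(dtype=float) if sex_col in table else None
    for name, kind in kinds.items():
        raw = table[name].to_numpy(dtype=float)
        EnvironmentTrait(name, kind, raw)  # validates
        if kind == "dichotomous":
            out[name] = raw
            continue
        z = inverse_normal_transform(raw, offset=offset)
        out[name] = residualize_trait(z, age=age, sex=sex, is_age=(name == age_col))
    return out
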