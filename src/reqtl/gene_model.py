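"""Gene-level expression arm: OLS interaction model.

Expression (inverse-normalized) is regressed on covariates, environment,
genotype dosage and their elementwise product; the interaction coefficient
is tested with a two-sided t-test at residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GeneModelSpec", "GeneGxeFit", "fit_gene_interaction"]


@dataclass
class GeneModelSpec:
    """Aligned design for one (gene, regulatory SNP, trait) test.

    ``Z`` holds the fixed covariates (intercept, batch indicators, genotype
    PCs, expression factors, optionally age/sex); ``e`` the environment;
    ``g`` the genotype dosage.
    """

    Z: np.ndarray
    e: np.ndarray
    g: np.ndarray
    z_names: list | None = None

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.e = np.asarray(self.e, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        n = self.e.shape[0]
        if self.Z.shape[0] != n or self.g.shape[0] != n:
            raise ValueError("design components must align over samples")


@dataclass
class GeneGxeFit:
    gamma_je: float
    gamma_jg: float
    beta: float
    alpha: np.ndarray
    se_beta: float
    df_resid: int
    p_value: float


def fit_gene_interaction(y, spec: GeneModelSpec) -> GeneGxeFit:
    """OLS fit of ``y = Z a + e g_e + g g_g + (g*e) b + noise``.

    Returns effect estimates and the two-sided t-test p-value for ``b = 0``.
    Raises on rank-deficient designs (naming the offending columns when
    possible) and on constant genotype or environment vectors.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("expression vector must be finite")
    if np.unique(spec.g).size < 2:
        raise ValueError("constant genotype vector")
    if np.ptp(spec.e) == 0:
        raise ValueError("constant environment vector")
    n = y.shape[0]
    X = np.column_stack([spec.Z, spec.e, spec.g, spec.g * spec.e])
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"need more samples ({n}) than parameters ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        names = (spec.z_names or [f"Z{i}" for i in range(spec.Z.shape[1])]) + ["e", "g", "g*e"]
        # identify columns whose removal restores full rank
        collinear = [
            names[j]
            for j in range(k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - k
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    beta = float(coef[-1])
    se_beta = float(se[-1])
    tstat = beta / se_beta if se_beta > 0 else np.inf * np.sign(beta)
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    nz = spec.Z.shape[1]
    return GeneGxeFit(
        gamma_je=float(coef[nz]),
        gamma_jg=float(coef[nz + 1]),
        beta=beta,
        alpha=coef[:nz].copy(),
        se_beta=se_beta,
        df_resid=df,
        p_value=max(p, np.finfo(float).tiny),
    )
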