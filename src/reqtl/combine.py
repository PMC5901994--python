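"""P-value combination, per-trait FDR control, and the headline report.

The two test arms (allele-specific and gene-level) are combined per
(gene, tSNP, trait) row with Fisher's method (chi-square, 4 df); q-values
are Benjamini-Hochberg within each trait; significant rows are reported
with one line per gene(-trait) pair, keeping the most significant tSNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CombinedResult", "fisher_combine", "bh_qvalues", "call_reqtls"]


@dataclass
class CombinedResult:
    gene_id: str
    trait: str
    reqtl_id: str
    tsnp_id: str
    p_ase: float
    p_gene: float
    p_combined: float | None = None
    q_value: float | None = None


def _check_p(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError(f"{name} must lie in (0, 1]")
    return p


def fisher_combine(p1, p2):
    """Fisher's combined probability of two independent p-values.

    ``X = -2(ln p1 + ln p2)`` referred to chi-square with 4 df, which has
    the closed form ``p1*p2*(1 - ln(p1*p2))``.  Symmetric; returns a value
    in (0, 1].  Accepts scalars or arrays.
    """
    p1 = _check_p(p1, "p1")
    p2 = _check_p(p2, "p2")
    x = -2.0 * (np.log(p1) + np.log(p2))
    out = stats.chi2.sf(x, df=4)
    return float(out) if out.ndim == 0 else out


def bh_qvalues(pvals):
    """Benjamini-Hochberg step-up q-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1; monotone
    non-decreasing in p.  Empty input yields empty output.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    _check_p(p, "pvals")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(q_sorted, None, 1.0, out=q_sorted)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_reqtls(
    results: pd.DataFrame,
    fdr: float = 0.10,
    *,
    per_gene: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine, FDR-control and report significant GxE results.

    Parameters
    ----------
    results
        One row per (gene, tSNP, trait) with columns ``gene_id``, ``trait``,
        ``tsnp_id``, ``p_ase``, ``p_gene`` (plus any annotation columns,
        carried through).
    fdr
        Per-trait FDR level for the headline table.
    per_gene
        When True (default) BH runs within trait over one combined p per
        gene — the minimum across that gene's tSNPs — and the gene's
        q-value is attached to all its rows.  When False BH runs over all
        gene-tSNP pairs within the trait.

    Returns
    -------
    (headline, pairs)
        ``headline``: rows with ``q_value <= fdr``, one per gene-trait pair
        (the most significant tSNP).  ``pairs``: the full per-pair table
        with ``p_combined`` and ``q_value`` columns added.
    """
    required = {"gene_id", "trait", "tsnp_id", "p_ase", "p_gene"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dup = results.duplicated(subset=["gene_id", "tsnp_id", "trait"])
    if dup.any():
        row = results.loc[dup.idxmax()]
        raise ValueError(
            f"duplicated (gene, tsnp, trait) row: "
            f"({row['gene_id']}, {row['tsnp_id']}, {row['trait']})"
        )
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")

    pairs = results.copy().reset_index(drop=True)
    pairs["p_combined"] = fisher_combine(pairs["p_ase"], pairs["p_gene"])

    pairs["q_value"] = np.nan
    for trait, idx in pairs.groupby("trait").groups.items():
        sub = pairs.loc[idx]
        if per_gene:
            gene_min = sub.groupby("gene_id")["p_combined"].min()
            q_gene = pd.Series(bh_qvalues(gene_min.to_numpy()), index=gene_min.index)
            pairs.loc[idx, "q_value"] = sub["gene_id"].map(q_gene).to_numpy()
        else:
            pairs.loc[idx, "q_value"] = bh_qvalues(sub["p_combined"].to_numpy())

    sig = pairs[pairs["q_value"] <= fdr]
    # one row per gene-trait pair: keep the most significant tSNP
    headline = (
        sig.sort_values(["trait", "gene_id", "p_combined"], kind="mergesort")
        .groupby(["trait", "gene_id"], as_index=False, sort=False)
        .first()
    )
    headline = headline.sort_values(["trait", "gene_id"], kind="mergesort").reset_index(drop=True)
    return headline, pairs
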