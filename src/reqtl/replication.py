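"""Discovery-to-replication comparison.

Per-gene minimum p-value selection, the replication-rate curve over
discovery p-value cutoffs, and a two-standard-deviation hypergeometric null
band around the overall replication fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ReplicationCurve", "min_p_per_gene", "replication_curve", "tsnp_count_balance"]


@dataclass
class ReplicationCurve:
    """Replication rate as a function of discovery p-value cutoff.

    ``rate = k/n`` where, at each cutoff, ``n`` discovery hits are selected
    and ``k`` of them replicate (replication p below ``rep_alpha``); the
    null band is ``K/N +/- 2*SD(k/n)`` with ``k`` hypergeometric(N, K, n).
    ``k_over_K`` (the replicated fraction of all nominal replication hits)
    is carried alongside.
    """

    cutoffs: np.ndarray
    n: np.ndarray
    k: np.ndarray
    rate: np.ndarray
    k_over_K: np.ndarray
    K: int
    N: int
    null_mean: float
    band_lo: np.ndarray
    band_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "n": self.n,
                "k": self.k,
                "rate": self.rate,
                "k_over_K": self.k_over_K,
                "null_mean": self.null_mean,
                "band_lo": self.band_lo,
                "band_hi": self.band_hi,
            }
        )


def min_p_per_gene(results: pd.DataFrame, p_col: str = "p_value") -> pd.Series:
    """Minimum p-value per gene (index: gene_id).

    Applied independently to discovery and replication result sets;
    singleton genes pass through.
    """
    if results.empty:
        return pd.Series(dtype=float)
    return results.groupby("gene_id")[p_col].min()


def replication_curve(
    disc: pd.Series,
    rep: pd.Series,
    rep_alpha: float = 0.01,
    min_n: int = 10,
) -> ReplicationCurve:
    """Replication-rate curve over descending discovery p-value cutoffs.

    ``disc`` and ``rep`` are per-gene minimum p-values indexed by gene and
    must share one gene universe.  Cutoffs iterate over sorted unique
    discovery p-values (descending); the curve stops once fewer than
    ``min_n`` discovery hits remain.
    """
    if set(disc.index) != set(rep.index):
        raise ValueError("discovery and replication gene universes differ")
    rep = rep.reindex(disc.index)
    d = disc.to_numpy(dtype=float)
    r = rep.to_numpy(dtype=float)
    N = d.size
    replicated = r < rep_alpha
    K = int(replicated.sum())

    cutoffs, ns, ks = [], [], []
    for cut in np.sort(np.unique(d))[::-1]:
        sel = d <= cut
        n = int(sel.sum())
        if n < min_n:
            break
        cutoffs.append(cut)
        ns.append(n)
        ks.append(int((sel & replicated).sum()))

    cutoffs = np.asarray(cutoffs)
    ns = np.asarray(ns, dtype=int)
    ks = np.asarray(ks, dtype=int)
    null_mean = K / N if N else np.nan
    var_k = np.array([stats.hypergeom(N, K, n).var() for n in ns])
    sd_rate = np.sqrt(var_k) / np.maximum(ns, 1)
    return ReplicationCurve(
        cutoffs=cutoffs,
        n=ns,
        k=ks,
        rate=ks / np.maximum(ns, 1),
        k_over_K=ks / K if K else np.full(ks.shape, np.nan),
        K=K,
        N=N,
        null_mean=null_mean,
        band_lo=null_mean - 2.0 * sd_rate,
        band_hi=null_mean + 2.0 * sd_rate,
    )


def tsnp_count_balance(replicated, not_replicated, tsnp_counts) -> tuple[float, float]:
    """Mean tSNP count in the replicated and non-replicated gene sets.

    ``tsnp_counts`` maps gene -> number of tSNPs.  Empty sets yield NaN.
    """
    replicated, not_replicated = set(replicated), set(not_replicated)
    if replicated & not_replicated:
        raise ValueError("replicated and not-replicated sets must be disjoint")
    counts = dict(tsnp_counts)

    def mean_of(genes):
        if not genes:
            return float("nan")
        return float(np.mean([counts[g] for g in genes]))

    return mean_of(replicated), mean_of(not_replicated)
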