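"""Allele-specific motif-disruption scoring.

Given per-allele motif-scan p-values (FIMO-style), the delta score
``-log10(p_alt) - (-log10(p_ref))`` quantifies predicted binding change;
positive values mean stronger predicted binding on the alternate allele.
An allele with no reported hit is substituted with p = 0.01, making the
score conservative.  Only records where at least one allele reaches the
scan's reporting threshold (1e-4) are scored.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["delta_score", "score_motif_table", "pivot_fimo_hits", "FALLBACK_P", "SCAN_THRESHOLD"]

FALLBACK_P = 0.01
SCAN_THRESHOLD = 1e-4


def delta_score(p_ref: float | None, p_alt: float | None) -> float:
    """Delta score for one variant x motif; missing alleles get p = 0.01."""
    if _missing(p_ref) and _missing(p_alt):
        raise ValueError("both alleles missing: nothing to score")
    pr = FALLBACK_P if _missing(p_ref) else _valid(p_ref, "p_ref")
    pa = FALLBACK_P if _missing(p_alt) else _valid(p_alt, "p_alt")
    return -math.log10(pa) + math.log10(pr)


def _missing(p) -> bool:
    return p is None or (isinstance(p, float) and math.isnan(p))


def _valid(p: float, name: str) -> float:
    if not 0 < p <= 1:
        raise ValueError(f"{name} must lie in (0, 1], got {p}")
    return float(p)


def pivot_fimo_hits(long_hits: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long scan table into per-variant p_ref/p_alt records.

    Expects FIMO-style columns ``motif_id``, ``sequence_name``, ``p-value``
    (or ``p_value``), where the sequence name encodes variant and allele as
    ``<variant>_ref`` / ``<variant>_alt``.  Multiple hits of the same motif
    on one sequence keep the best (smallest) p-value.
    """
    df = long_hits.rename(columns={"p-value": "p_value"}).copy()
    parts = df["sequence_name"].str.rsplit("_", n=1, expand=True)
    if parts.shape[1] < 2:
        raise ValueError(
            f"sequence name must end in _ref or _alt: {df['sequence_name'].iloc[0]!r}"
        )
    if (~parts[1].isin(["ref", "alt"])).any():
        bad = df.loc[~parts[1].isin(["ref", "alt"]), "sequence_name"].iloc[0]
        raise ValueError(f"sequence name must end in _ref or _alt: {bad!r}")
    df["variant_id"], df["allele"] = parts[0], parts[1]
    best = (
        df.groupby(["variant_id", "motif_id", "allele"])["p_value"].min().unstack("allele")
    )
    best = best.rename(columns={"ref": "p_ref", "alt": "p_alt"}).reset_index()
    for col in ("p_ref", "p_alt"):
        if col not in best:
            best[col] = float("nan")
    return best[["variant_id", "motif_id", "p_ref", "p_alt"]]


def score_motif_table(hits: pd.DataFrame, threshold: float = SCAN_THRESHOLD) -> pd.DataFrame:
    """Score a table of per-allele motif hits.

    Expects columns ``variant_id``, ``motif_id``, ``p_ref``, ``p_alt``
    (NaN = no hit for that allele).  Records where neither allele reaches
    ``threshold`` are dropped, not scored.
    """
    df = hits.copy()
    pr = df["p_ref"].to_numpy(dtype=float)
    pa = df["p_alt"].to_numpy(dtype=float)
    best = np.fmin(pr, pa)  # NaN-ignoring minimum
    keep = ~np.isnan(best) & (best <= threshold)
    df = df[keep].reset_index(drop=True)
    df["delta"] = [
        delta_score(None if np.isnan(r) else r, None if np.isnan(a) else a)
        for r, a in zip(df["p_ref"], df["p_alt"])
    ]
    return df
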