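"""Quality control for allelic count tables and testability screens.

Three layers of filtering are applied before any modeling:

1. tSNP-level mapping-bias exclusion based on simulated-read coverage and
   allele balance.
2. Observation/tSNP-level count filters: per-observation read depth, number
   of heterozygous carriers, and a mono-allelic expression screen.
3. Per-test eligibility: genotype-class counts at the candidate regulatory
   SNP, with group-size requirements for dichotomous environments.

All filters are pure functions over pandas DataFrames and return provenance
counts so that a run log can account for every removed unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QcConfig",
    "QcReport",
    "mapping_bias_filter",
    "count_filters",
    "test_eligibility",
]

#: required columns of an allelic count table
COUNT_COLUMNS = ("sample_id", "tsnp_id", "chrom", "pos", "ref_count", "alt_count")


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for all QC and eligibility filters.

    Defaults follow the discovery analysis this package implements:
    per-observation coverage >= 30 reads, tSNPs heterozygous in >= 20
    samples, mono-allelic exclusion at |0.5 - alt/total| > 0.4, simulated
    coverage retained in [193, 202] with allele ratio within 5% of 0.5,
    and per-test genotype-group minima of 15/15 with dichotomous cells of
    at least 5 samples.
    """

    min_reads_per_obs: int = 30
    min_het_samples: int = 20
    monoallelic_dev: float = 0.4
    sim_cov_min: int = 193
    sim_cov_max: int = 202
    sim_ratio_dev: float = 0.05
    min_hom: int = 15
    min_het_eqtl: int = 15
    min_group: int = 5

    def __post_init__(self) -> None:
        for name in (
            "min_reads_per_obs",
            "min_het_samples",
            "monoallelic_dev",
            "sim_cov_min",
            "sim_cov_max",
            "sim_ratio_dev",
            "min_hom",
            "min_het_eqtl",
            "min_group",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"QcConfig.{name} must be >= 0")


@dataclass
class QcReport:
    """Per-step removal counts for a QC run (input = retained + removed)."""

    n_input: int = 0
    n_removed_low_reads: int = 0
    n_removed_few_hets: int = 0
    n_removed_monoallelic: int = 0
    n_retained: int = 0
    tsnps_input: int = 0
    tsnps_retained: int = 0
    steps: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_low_reads": self.n_removed_low_reads,
            "n_removed_few_hets": self.n_removed_few_hets,
            "n_removed_monoallelic": self.n_removed_monoallelic,
            "n_retained": self.n_retained,
            "tsnps_input": self.tsnps_input,
            "tsnps_retained": self.tsnps_retained,
            "steps": list(self.steps),
        }


def mapping_bias_filter(stats: pd.DataFrame, cfg: QcConfig | None = None) -> set:
    """Retain tSNPs whose simulated-read coverage and allele ratio look unbiased.

    Parameters
    ----------
    stats
        DataFrame with columns ``tsnp_id``, ``sim_total``, ``sim_allele_ratio``;
        one row per tSNP.
    cfg
        Thresholds; defaults used when omitted.

    Returns
    -------
    set
        tSNP ids with ``sim_cov_min <= sim_total <= sim_cov_max`` and
        ``|sim_allele_ratio - 0.5| < sim_ratio_dev``.
    """
    cfg = cfg or QcConfig()
    dup = stats["tsnp_id"][stats["tsnp_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate tsnp_id in mapping-bias stats: {dup.iloc[0]!r}")
    total = stats["sim_total"].to_numpy()
    ratio = stats["sim_allele_ratio"].to_numpy(dtype=float)
    if (ratio < 0).any() or (ratio > 1).any():
        raise ValueError("sim_allele_ratio must lie in [0, 1]")
    keep = (
        (total >= cfg.sim_cov_min)
        & (total <= cfg.sim_cov_max)
        & (np.abs(ratio - 0.5) < cfg.sim_ratio_dev)
    )
    return set(stats.loc[keep, "tsnp_id"])


def count_filters(
    records: pd.DataFrame,
    het_map: Mapping[tuple, bool] | pd.DataFrame,
    cfg: QcConfig | None = None,
) -> tuple[pd.DataFrame, set, QcReport]:
    """Apply the three sequential count filters to an allelic count table.

    Order is fixed: (1) drop observations with fewer than
    ``min_reads_per_obs`` total reads; (2) drop tSNPs heterozygous in fewer
    than ``min_het_samples`` surviving samples; (3) drop tSNPs for which any
    surviving sample shows near mono-allelic expression,
    ``|0.5 - alt/total| > monoallelic_dev``.

    Parameters
    ----------
    records
        Allelic count table with columns :data:`COUNT_COLUMNS`.
    het_map
        Either a mapping ``(sample_id, tsnp_id) -> bool`` or a DataFrame with
        columns ``sample_id``, ``tsnp_id``, ``het``; must cover every record.
    cfg
        Thresholds.

    Returns
    -------
    (filtered records, retained tSNP id set, QcReport)
    """
    cfg = cfg or QcConfig()
    report = QcReport(n_input=len(records), tsnps_input=records["tsnp_id"].nunique())

    if isinstance(het_map, pd.DataFrame):
        het_lookup = {
            (s, t): bool(h)
            for s, t, h in zip(het_map["sample_id"], het_map["tsnp_id"], het_map["het"])
        }
    else:
        het_lookup = dict(het_map)

    keys = list(zip(records["sample_id"], records["tsnp_id"]))
    missing = [k for k in keys if k not in het_lookup]
    if missing:
        raise ValueError(f"het_map does not cover record {missing[0]!r}")

    df = records.copy()
    total = df["ref_count"].to_numpy() + df["alt_count"].to_numpy()
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        raise ValueError("negative read counts")

    # step 1: per-observation coverage
    df = df[total >= cfg.min_reads_per_obs]
    report.n_removed_low_reads = report.n_input - len(df)
    report.steps.append(("low_reads", report.n_removed_low_reads))

    # step 2: heterozygous carrier count among surviving observations
    is_het = np.array(
        [het_lookup[(s, t)] for s, t in zip(df["sample_id"], df["tsnp_id"])], dtype=bool
    )
    het_counts = (
        pd.Series(is_het, index=df.index).groupby(df["tsnp_id"]).sum()
        if len(df)
        else pd.Series(dtype=int)
    )
    ok_tsnps = set(het_counts[het_counts >= cfg.min_het_samples].index)
    before = len(df)
    df = df[df["tsnp_id"].isin(ok_tsnps)]
    report.n_removed_few_hets = before - len(df)
    report.steps.append(("few_hets", report.n_removed_few_hets))

    # step 3: mono-allelic screen — one extreme sample kills the tSNP
    tot = df["ref_count"].to_numpy() + df["alt_count"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = np.abs(0.5 - df["alt_count"].to_numpy() / tot)
    bad_tsnps = set(df.loc[dev > cfg.monoallelic_dev, "tsnp_id"])
    before = len(df)
    df = df[~df["tsnp_id"].isin(bad_tsnps)]
    report.n_removed_monoallelic = before - len(df)
    report.steps.append(("monoallelic", report.n_removed_monoallelic))

    report.n_retained = len(df)
    retained = set(df["tsnp_id"])
    report.tsnps_retained = len(retained)
    return df.reset_index(drop=True), retained, report


def test_eligibility(
    eqtl_genotypes: Iterable,
    env: Iterable,
    cfg: QcConfig | None = None,
    env_kind: str = "continuous",
) -> tuple[bool, str]:
    """Decide whether a candidate regulatory SNP/trait pair is testable.

    Genotype classes must be in {0, 1, 2} (``1`` = heterozygous; both
    homozygote classes count together toward the homozygote minimum).
    Samples with missing environment are excluded before counting. For a
    dichotomous environment every heterozygosity-class x env-level cell must
    hold at least ``min_group`` samples.

    Returns ``(eligible, reason)`` where ``reason`` is ``"ok"`` when eligible.
    """
    cfg = cfg or QcConfig()
    g = np.asarray(list(eqtl_genotypes), dtype=float)
    e = np.asarray(list(env), dtype=float)
    if g.shape != e.shape:
        raise ValueError("genotype and environment vectors must align")
    if not np.isin(g[~np.isnan(g)], [0.0, 1.0, 2.0]).all():
        raise ValueError("genotype classes must be 0/1/2")

    obs = ~np.isnan(e) & ~np.isnan(g)
    if not obs.any():
        raise ValueError("environment has zero non-missing values")
    g, e = g[obs], e[obs]

    n_het = int((g == 1).sum())
    n_hom = int(((g == 0) | (g == 2)).sum())
    if n_hom < cfg.min_hom:
        return False, f"hom<{cfg.min_hom}"
    if n_het < cfg.min_het_eqtl:
        return False, f"het<{cfg.min_het_eqtl}"
    if env_kind == "dichotomous":
        levels = np.unique(e)
        if not np.isin(levels, [0.0, 1.0]).all():
            raise ValueError("dichotomous environment must be coded 0/1")
        het = (g == 1).astype(int)
        for hval in (0, 1):
            for eval_ in (0.0, 1.0):
                cell = int(((het == hval) & (e == eval_)).sum())
                if cell < cfg.min_group:
                    return False, f"group<{cfg.min_group}"
    return True, "ok"
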