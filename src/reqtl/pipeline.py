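"""End-to-end discovery orchestration.

Composes the stages in their analysis order — count QC, trait preparation,
per-unit eligibility, the allele-specific and gene-level interaction fits,
Fisher combination and per-trait FDR — over a file-based run configuration.
Every skipped or failed unit is logged with its reason; a run is
reproducible byte-for-byte from the same inputs and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .ase_model import AseGxeDesign, IGPrior, estimate_ig_prior, fit_ase_gxe, fit_tsnp_variance
from .ase_qc import QcConfig, count_filters, test_eligibility
from .combine import call_reqtls
from .gene_model import GeneModelSpec, fit_gene_interaction
from .phenotypes import prepare_traits

logger = logging.getLogger("reqtl")

__all__ = ["RunConfig", "run_discovery"]


@dataclass
class RunConfig:
    """Paths and settings for a discovery run (YAML-loadable)."""

    counts: str
    vcf: str
    expression: str
    traits: str
    covariates: str
    candidates: str
    trait_kinds: dict
    outdir: str
    fdr: float = 0.10
    qc: QcConfig = field(default_factory=QcConfig)
    prior: IGPrior | None = None
    learn_prior: bool = True
    seed: int = 0
    likelihood: str = "folded"
    age_col: str = "age"
    sex_col: str = "sex"
    pc_cols: tuple = ("PC1", "PC2")
    gene_cov_cols: tuple = ("batch", "PC1", "PC2", "PEER1", "PEER2")

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        qc = QcConfig(**raw.pop("qc", {}))
        prior = raw.pop("prior", None)
        prior = IGPrior(**prior) if prior else None
        return cls(qc=qc, prior=prior, **raw)

    def check_files(self) -> None:
        for name in ("counts", "vcf", "expression", "traits", "covariates", "candidates"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _het_map_from_dosages(dosages: pd.DataFrame, counts: pd.DataFrame) -> dict:
    het = {}
    for s, t in zip(counts["sample_id"], counts["tsnp_id"]):
        if t in dosages.columns and s in dosages.index:
            het[(s, t)] = bool(np.round(dosages.at[s, t]) == 1)
        else:
            het[(s, t)] = True  # assume het when genotype absent (counts imply it)
    return het


def run_discovery(cfg: RunConfig) -> dict:
    """Run discovery end to end; returns paths of the written artifacts."""
    cfg.check_files()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"skipped": [], "counts": {}}

    counts = io.read_counts_tsv(cfg.counts)
    dosages = io.read_vcf_genotypes(cfg.vcf)
    expression = pd.read_csv(cfg.expression, sep="\t", index_col=0)
    trait_table = io.read_trait_table(cfg.traits)
    covariates = io.read_trait_table(cfg.covariates)
    candidates = pd.read_csv(cfg.candidates, sep="\t")

    # stage 1: count QC
    het_map = _het_map_from_dosages(dosages, counts)
    filtered, retained_tsnps, qc_report = count_filters(counts, het_map, cfg.qc)
    log["counts"]["qc"] = qc_report.to_dict()

    # stage 2: trait preparation — per trait, so one bad trait cannot stop
    # the rest of the run
    env = pd.DataFrame(index=trait_table.index)
    usable_traits = {}
    for name, kind in cfg.trait_kinds.items():
        try:
            env[name] = prepare_traits(
                trait_table, {name: kind}, age_col=cfg.age_col, sex_col=cfg.sex_col
            )[name]
            usable_traits[name] = kind
        except (KeyError, ValueError) as exc:
            log["skipped"].append({"unit": f"trait:{name}", "reason": f"unusable trait: {exc}"})

    # stage 3: empirical-Bayes prior over per-tSNP variances (optional)
    prior = cfg.prior
    if prior is None and cfg.learn_prior:
        vhats = []
        for t, sub in filtered.groupby("tsnp_id"):
            n = sub["ref_count"].to_numpy() + sub["alt_count"].to_numpy()
            vhats.append(fit_tsnp_variance(n, sub["alt_count"].to_numpy())[1])
        try:
            prior = estimate_ig_prior(vhats)
        except ValueError as exc:
            logger.warning("prior learning failed (%s); using default", exc)
            prior = IGPrior(1.80, 0.0024)
    elif prior is None:
        prior = IGPrior(1.80, 0.0024)
    log["prior"] = {"a": prior.a, "b": prior.b}

    pc_cols = [c for c in cfg.pc_cols if c in covariates.columns]
    rows = []
    for trait in usable_traits:
        e_all = env[trait]
        for _, cand in candidates.drop_duplicates(["gene_id", "reqtl_id"]).iterrows():
            gene, reqtl = cand["gene_id"], cand["reqtl_id"]
            unit = f"{gene}/{reqtl}/{trait}"
            try:
                samples = [s for s in expression.columns if s in e_all.index]
                g = np.round(dosages.loc[samples, reqtl].to_numpy(dtype=float))
                e = e_all.loc[samples].to_numpy(dtype=float)
                ok, reason = test_eligibility(g, e, cfg.qc, env_kind=usable_traits[trait])
                if not ok:
                    log["skipped"].append({"unit": unit, "reason": reason})
                    continue
                obs = ~np.isnan(e) & ~np.isnan(g)
                use = [s for s, o in zip(samples, obs) if o]
                g_u = np.round(dosages.loc[use, reqtl].to_numpy(dtype=float))
                e_u = e_all.loc[use].to_numpy(dtype=float)

                # gene arm
                zc = [c for c in cfg.gene_cov_cols if c in covariates.columns]
                Z = [np.ones(len(use))]
                names = ["intercept"]
                for c in zc:
                    Z.append(covariates.loc[use, c].to_numpy(dtype=float))
                    names.append(c)
                if trait != cfg.age_col and cfg.age_col in trait_table.columns:
                    Z.append(trait_table.loc[use, cfg.age_col].to_numpy(dtype=float))
                    names.append(cfg.age_col)
                if trait != cfg.sex_col and cfg.sex_col in trait_table.columns:
                    Z.append(trait_table.loc[use, cfg.sex_col].to_numpy(dtype=float))
                    names.append(cfg.sex_col)
                spec = GeneModelSpec(Z=np.column_stack(Z), e=e_u, g=g_u, z_names=names)
                gene_fit = fit_gene_interaction(
                    expression.loc[gene, use].to_numpy(dtype=float), spec
                )

                # ASE arm, one test per tSNP of this gene
                tsnps = candidates.loc[candidates["gene_id"] == gene, "tsnp_id"].unique()
                for tsnp in tsnps:
                    if tsnp not in retained_tsnps:
                        log["skipped"].append({"unit": f"{unit}@{tsnp}", "reason": "tsnp filtered"})
                        continue
                    sub = filtered[
                        (filtered["tsnp_id"] == tsnp) & filtered["sample_id"].isin(use)
                    ]
                    idx = sub["sample_id"].tolist()
                    h = (np.round(dosages.loc[idx, reqtl].to_numpy(dtype=float)) == 1).astype(float)
                    cov = (
                        covariates.loc[idx, pc_cols].to_numpy(dtype=float)
                        if pc_cols
                        else None
                    )
                    design = AseGxeDesign(
                        n=sub["ref_count"].to_numpy() + sub["alt_count"].to_numpy(),
                        y=sub["alt_count"].to_numpy(),
                        e=e_all.loc[idx].to_numpy(dtype=float),
                        h=h,
                        covariates=cov,
                    )
                    try:
                        full, _ = fit_ase_gxe(design, prior, likelihood=cfg.likelihood)
                    except ValueError as exc:
                        log["skipped"].append({"unit": f"{unit}@{tsnp}", "reason": str(exc)})
                        continue
                    if not full.converged:
                        log["skipped"].append({"unit": f"{unit}@{tsnp}", "reason": "non-convergence"})
                        continue
                    rows.append(
                        {
                            "gene_id": gene,
                            "trait": trait,
                            "reqtl_id": reqtl,
                            "tsnp_id": tsnp,
                            "p_ase": full.p_value,
                            "p_gene": gene_fit.p_value,
                            "beta_seh": full.beta_seh,
                            "v_s": full.v,
                            "beta_gene": gene_fit.beta,
                        }
                    )
            except Exception as exc:  # keep going over remaining units
                log["skipped"].append({"unit": unit, "reason": f"error: {exc}"})

    results = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "trait", "reqtl_id", "tsnp_id",
            "p_ase", "p_gene", "beta_seh", "v_s", "beta_gene",
        ],
    )
    artifacts = {"results": str(outdir / "pairs.tsv"), "log": str(outdir / "run_log.json")}
    if len(results):
        headline, pairs = call_reqtls(results, fdr=cfg.fdr)
        headline.to_csv(outdir / "headline.tsv", sep="\t", index=False)
        pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        artifacts["headline"] = str(outdir / "headline.tsv")
        log["counts"]["tested_pairs"] = int(len(pairs))
        log["counts"]["headline_rows"] = int(len(headline))
    else:
        pd.DataFrame(columns=results.columns).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        log["counts"]["tested_pairs"] = 0
        log["counts"]["headline_rows"] = 0
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return artifacts
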