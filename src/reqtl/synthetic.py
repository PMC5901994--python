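"""Synthetic data with the statistical structure the pipeline assumes.

Generates phased genotypes for a candidate regulatory SNP and its
transcribed SNPs (Hardy-Weinberg, configurable haplotype LD), environment
traits, overdispersed allelic read counts from the binomial-logistic GxE
model (random-effect variances drawn from an inverse-gamma), and gene
expression from the linear interaction model with confounders.  Every draw
is reproducible from the seed, and generating parameters are recorded so
recovery tests can compare against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .ase_model import AseGxeDesign, IGPrior

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_ase_counts",
    "simulate_expression",
    "simulate_dataset",
    "calibration_study",
]


@dataclass
class SimConfig:
    """All knobs of the generator.  ``seed`` is mandatory."""

    seed: int
    n_samples: int = 300
    n_tsnps: int = 1
    maf_reqtl: float = 0.5
    maf_tsnp: float = 0.5
    ld_r2: float = 0.0
    env_kind: str = "continuous"  # or "dichotomous"
    depth_mean: float = 60.0
    depth_dispersion: float = 0.2
    prior: IGPrior = field(default_factory=lambda: IGPrior(1.80, 0.0024))
    # ASE-arm effects
    gamma_se: float = 0.0
    gamma_sh: float = 0.0
    beta_seh: float = 0.0
    mu_s: float = 0.0
    # gene-arm effects
    gamma_je: float = 0.0
    gamma_jg: float = 0.0
    beta_j: float = 0.0
    noise_sd: float = 1.0
    # confounders
    n_batches: int = 2
    pc_scale: float = 0.5
    peer_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f in ("maf_reqtl", "maf_tsnp"):
            p = getattr(self, f)
            if not 0 < p < 1:
                raise ValueError(f"{f} must lie in (0, 1)")
        if not 0 <= self.ld_r2 <= 1:
            raise ValueError("ld_r2 must lie in [0, 1]")
        if self.env_kind not in ("continuous", "dichotomous"):
            raise ValueError("env_kind must be continuous or dichotomous")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticTruth:
    """Generating parameters and latent state recorded for recovery tests."""

    config: dict
    v_s: np.ndarray | None = None
    eps: dict | None = None
    alpha: np.ndarray | None = None
    Z: np.ndarray | None = None


def _max_abs_r(p1: float, p2: float) -> float:
    q1, q2 = 1 - p1, 1 - p2
    d_max = min(p1 * q2, q1 * p2)
    d_min = min(p1 * p2, q1 * q2)
    denom = np.sqrt(p1 * q1 * p2 * q2)
    return min(d_max, d_min) / denom  # symmetric bound used for validation


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Phased genotypes for the regulatory SNP and each tSNP.

    Returns ``(reqtl_hap, tsnp_hap)`` with shapes (n_samples, 2) and
    (n_tsnps, n_samples, 2); haplotype correlation between the regulatory
    and transcribed alleles is ``sqrt(ld_r2)`` (positive phase).
    """
    rng = rng or cfg.rng()
    p1, p2 = cfg.maf_reqtl, cfg.maf_tsnp
    r = float(np.sqrt(cfg.ld_r2))
    d = r * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    p_b_given_a1 = p2 + d / p1
    p_b_given_a0 = p2 - d / (1 - p1)
    if not (0 <= p_b_given_a1 <= 1 and 0 <= p_b_given_a0 <= 1):
        raise ValueError(
            f"ld_r2={cfg.ld_r2} infeasible for MAFs ({p1}, {p2}); "
            f"|r| must be <= {_max_abs_r(p1, p2):.4f}"
        )
    reqtl_hap = (rng.random((cfg.n_samples, 2)) < p1).astype(np.int8)
    cond = np.where(reqtl_hap == 1, p_b_given_a1, p_b_given_a0)
    tsnp_hap = (rng.random((cfg.n_tsnps, cfg.n_samples, 2)) < cond[None]).astype(np.int8)
    return reqtl_hap, tsnp_hap


def simulate_environment(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Environment vector: standard normal, or Bernoulli(0.5) coded 0/1."""
    rng = rng or cfg.rng()
    if cfg.env_kind == "continuous":
        return rng.standard_normal(cfg.n_samples)
    return rng.integers(0, 2, cfg.n_samples).astype(float)


def _negbin_depth(rng, size, mean, dispersion):
    if dispersion <= 0:
        return rng.poisson(mean, size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size)
    return rng.poisson(lam)


def simulate_ase_counts(
    reqtl_hap: np.ndarray,
    tsnp_hap: np.ndarray,
    env: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Allelic count records for tSNP-heterozygous samples, plus truth.

    For each tSNP ``v_s ~ IG(a, b)``; per observation ``eps ~ N(0, v_s)``
    and the read fraction of the signal haplotype (the one carrying the
    regulatory alternate allele) is ``sigmoid(e*g_se + h*g_sh + e*h*b_seh
    + mu_s + eps)``.  Counts are reported unfolded with phase-consistent
    allele assignment.
    """
    rng = rng or cfg.rng()
    n_tsnps, n_samples, _ = tsnp_hap.shape
    g_reqtl = reqtl_hap.sum(axis=1)
    h = (g_reqtl == 1).astype(float)
    a, b = cfg.prior.a, cfg.prior.b
    v_s = 1.0 / rng.gamma(a, 1.0 / b, n_tsnps)  # IG(a, b) draws
    rows = []
    eps_store: dict = {}
    for s in range(n_tsnps):
        het = tsnp_hap[s, :, 0] != tsnp_hap[s, :, 1]
        idx = np.flatnonzero(het)
        depth = _negbin_depth(rng, idx.size, cfg.depth_mean, cfg.depth_dispersion)
        eps = rng.normal(0.0, np.sqrt(v_s[s]), idx.size)
        eta = (
            env[idx] * cfg.gamma_se
            + h[idx] * cfg.gamma_sh
            + env[idx] * h[idx] * cfg.beta_seh
            + cfg.mu_s
            + eps
        )
        p_signal = expit(eta)
        # phase: is the tSNP alt allele on the haplotype carrying the
        # regulatory alt allele?  (for h=0 the orientation is arbitrary
        # and taken from haplotype 1)
        alt_on_h1 = tsnp_hap[s, idx, 0] == 1
        signal_h1 = np.where(h[idx] == 1, reqtl_hap[idx, 0] == 1, True)
        cis = alt_on_h1 == signal_h1
        p_alt = np.where(cis, p_signal, 1.0 - p_signal)
        y_alt = rng.binomial(depth, p_alt)
        eps_store[s] = eps
        for j, i in enumerate(idx):
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "tsnp_id": f"ts{s}",
                    "chrom": "1",
                    "pos": 1000 + s,
                    "ref_count": int(depth[j] - y_alt[j]),
                    "alt_count": int(y_alt[j]),
                    "h": h[i],
                    "e": env[i],
                    "cis": bool(cis[j]),
                }
            )
    counts = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "tsnp_id", "chrom", "pos",
            "ref_count", "alt_count", "h", "e", "cis",
        ],
    )
    truth = SyntheticTruth(config=_cfg_dict(cfg), v_s=v_s, eps=eps_store)
    return counts, truth


def design_from_counts(counts: pd.DataFrame, tsnp_id: str, covariates=None) -> AseGxeDesign:
    """Build a model design from one simulated tSNP's count records."""
    sub = counts[counts["tsnp_id"] == tsnp_id]
    return AseGxeDesign(
        n=sub["ref_count"].to_numpy() + sub["alt_count"].to_numpy(),
        y=sub["alt_count"].to_numpy(),
        e=sub["e"].to_numpy(dtype=float),
        h=sub["h"].to_numpy(dtype=float),
        covariates=covariates,
    )


def simulate_expression(
    reqtl_hap: np.ndarray,
    env: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    alpha: np.ndarray | None = None,
):
    """Gene expression from the linear interaction model with confounders.

    ``y = Z alpha + e*g_je + g*g_jg + (g*e)*b_j + N(0, noise_sd^2)`` where Z
    holds an intercept, batch indicators and four latent-factor-style
    covariates (two "PC"-like, two "PEER"-like).
    Returns ``(y, Z, truth)``.
    """
    rng = rng or cfg.rng()
    n = env.shape[0]
    g = reqtl_hap.sum(axis=1).astype(float)
    cols = [np.ones(n)]
    batch = rng.integers(0, cfg.n_batches, n)
    for bb in range(1, cfg.n_batches):
        cols.append((batch == bb).astype(float))
    cols.append(cfg.pc_scale * rng.standard_normal(n))
    cols.append(cfg.pc_scale * rng.standard_normal(n))
    cols.append(cfg.peer_scale * rng.standard_normal(n))
    cols.append(cfg.peer_scale * rng.standard_normal(n))
    Z = np.column_stack(cols)
    if alpha is None:
        alpha = rng.normal(0.0, 0.5, Z.shape[1])
    y = (
        Z @ alpha
        + env * cfg.gamma_je
        + g * cfg.gamma_jg
        + g * env * cfg.beta_j
        + rng.normal(0.0, cfg.noise_sd, n)
    )
    truth = SyntheticTruth(config=_cfg_dict(cfg), alpha=np.asarray(alpha), Z=Z)
    return y, Z, truth


def simulate_dataset(cfg: SimConfig):
    """One coherent dataset: genotypes, environment, counts, expression.

    Returns a dict with keys ``reqtl_hap``, ``tsnp_hap``, ``env``,
    ``counts``, ``expression``, ``Z``, ``truth_ase``, ``truth_gene``.
    """
    rng = cfg.rng()
    reqtl_hap, tsnp_hap = simulate_genotypes(cfg, rng)
    env = simulate_environment(cfg, rng)
    counts, truth_ase = simulate_ase_counts(reqtl_hap, tsnp_hap, env, cfg, rng)
    y, Z, truth_gene = simulate_expression(reqtl_hap, env, cfg, rng)
    return {
        "reqtl_hap": reqtl_hap,
        "tsnp_hap": tsnp_hap,
        "env": env,
        "counts": counts,
        "expression": y,
        "Z": Z,
        "truth_ase": truth_ase,
        "truth_gene": truth_gene,
    }


def calibration_study(cfg: SimConfig, n_reps: int = 200, alphas=(0.05, 0.01)) -> dict:
    """Empirical rejection rates and QQ data over replicate simulations.

    Each replicate draws a fresh dataset from ``cfg`` (seed advanced per
    replicate), fits the allele-specific and gene-level arms and the
    Fisher combination, and records all three p-values.
    """
    from dataclasses import replace

    from .ase_model import fit_ase_gxe
    from .combine import fisher_combine
    from .gene_model import GeneModelSpec, fit_gene_interaction

    p_ase, p_gene = [], []
    for rep in range(n_reps):
        c = replace(cfg, seed=cfg.seed + rep)
        data = simulate_dataset(c)
        design = design_from_counts(data["counts"], "ts0")
        full, _ = fit_ase_gxe(design, c.prior)
        p_ase.append(full.p_value)
        spec = GeneModelSpec(Z=data["Z"], e=data["env"], g=data["reqtl_hap"].sum(axis=1))
        p_gene.append(fit_gene_interaction(data["expression"], spec).p_value)
    p_ase = np.asarray(p_ase)
    p_gene = np.asarray(p_gene)
    p_comb = fisher_combine(p_ase, p_gene)
    expected = (np.arange(1, n_reps + 1) - 0.5) / n_reps
    return {
        "p_ase": p_ase,
        "p_gene": p_gene,
        "p_combined": p_comb,
        "rejection": {
            arm: {a: float(np.mean(p <= a)) for a in alphas}
            for arm, p in (("ase", p_ase), ("gene", p_gene), ("combined", p_comb))
        },
        "qq_expected": expected,
        "qq_observed": {
            "ase": np.sort(p_ase),
            "gene": np.sort(p_gene),
            "combined": np.sort(p_comb),
        },
    }


def write_dataset(cfg: SimConfig, outdir) -> dict:
    """Write one simulated dataset as the file set the discovery run reads.

    Produces VCF (regulatory SNP + tSNPs, phased GT), allelic count TSV,
    expression TSV (genes x samples), trait TSV (environment plus age and
    sex covariate columns), covariate TSV, candidate list TSV and a truth
    JSON.  Returns the path mapping.
    """
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(cfg)
    rng = np.random.default_rng(cfg.seed + 104729)  # covariate-only stream
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]

    variants = [
        {"chrom": "1", "pos": 500, "id": "rq0", "ref": "A", "alt": "G",
         "genotypes": data["reqtl_hap"]}
    ]
    for s in range(cfg.n_tsnps):
        variants.append(
            {"chrom": "1", "pos": 1000 + s, "id": f"ts{s}", "ref": "C", "alt": "T",
             "genotypes": data["tsnp_hap"][s]}
        )
    io.write_vcf(outdir / "genotypes.vcf", samples, variants)

    counts = data["counts"][["sample_id", "tsnp_id", "chrom", "pos", "ref_count", "alt_count"]]
    counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)

    expr = pd.DataFrame([data["expression"]], index=["G0"], columns=samples)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")

    traits = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    traits["env"] = data["env"]
    traits["age"] = rng.uniform(40, 70, cfg.n_samples).round(1)
    traits["sex"] = rng.integers(0, 2, cfg.n_samples)
    traits.to_csv(outdir / "traits.tsv", sep="\t")

    Z = data["Z"]
    cov = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    cov["batch"] = Z[:, 1] if cfg.n_batches > 1 else 0.0
    ofs = cfg.n_batches  # intercept + batch indicators
    cov["PC1"], cov["PC2"] = Z[:, ofs], Z[:, ofs + 1]
    cov["PEER1"], cov["PEER2"] = Z[:, ofs + 2], Z[:, ofs + 3]
    cov.to_csv(outdir / "covariates.tsv", sep="\t")

    cand = pd.DataFrame(
        {"gene_id": "G0", "reqtl_id": "rq0", "tsnp_id": [f"ts{s}" for s in range(cfg.n_tsnps)]}
    )
    cand.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    io.write_json(
        {"config": _cfg_dict(cfg), "v_s": data["truth_ase"].v_s,
         "alpha": data["truth_gene"].alpha},
        outdir / "truth.json",
    )
    return {
        "counts": str(outdir / "counts.tsv"),
        "vcf": str(outdir / "genotypes.vcf"),
        "expression": str(outdir / "expression.tsv"),
        "traits": str(outdir / "traits.tsv"),
        "covariates": str(outdir / "covariates.tsv"),
        "candidates": str(outdir / "candidates.tsv"),
        "truth": str(outdir / "truth.json"),
    }


def _cfg_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["prior"] = {"a": cfg.prior.a, "b": cfg.prior.b}
    return d
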