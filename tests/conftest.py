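import numpy as np
import pandas as pd
import pytest

from reqtl.ase_model import IGPrior
from reqtl.synthetic import (
    SimConfig,
    design_from_counts,
    simulate_ase_counts,
    simulate_environment,
    simulate_genotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def prior():
    return IGPrior(1.80, 0.0024)


def simulate_ase_design(seed, n_samples=300, depth_mean=60, **effects):
    """One simulated tSNP's model design (bypasses QC)."""
    cfg = SimConfig(seed=seed, n_samples=n_samples, n_tsnps=1, depth_mean=depth_mean, **effects)
    gen = cfg.rng()
    reqtl_hap, tsnp_hap = simulate_genotypes(cfg, gen)
    env = simulate_environment(cfg, gen)
    counts, truth = simulate_ase_counts(reqtl_hap, tsnp_hap, env, cfg, gen)
    return design_from_counts(counts, "ts0"), truth


@pytest.fixture
def count_table():
    """Small hand-built allelic count table with known filter outcomes."""
    rows = []
    for i in range(25):
        rows.append(("S%02d" % i, "tsA", "1", 100, 20, 20))  # clean, 40 reads
    for i in range(25):
        rows.append(("S%02d" % i, "tsB", "1", 200, 15, 14))  # 29 reads -> dropped
    for i in range(25):
        rows.append(("S%02d" % i, "tsC", "1", 300, 2, 38))   # monoallelic 0.95
    return pd.DataFrame(
        rows, columns=["sample_id", "tsnp_id", "chrom", "pos", "ref_count", "alt_count"]
    )


@pytest.fixture
def het_all(count_table):
    return {(s, t): True for s, t in zip(count_table["sample_id"], count_table["tsnp_id"])}
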