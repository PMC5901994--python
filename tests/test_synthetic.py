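import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reqtl.ase_model import IGPrior, fit_ase_gxe
from reqtl.ase_qc import count_filters
from reqtl.combine import fisher_combine
from reqtl.gene_model import GeneModelSpec, fit_gene_interaction
from reqtl.synthetic import (
    SimConfig,
    calibration_study,
    design_from_counts,
    simulate_ase_counts,
    simulate_dataset,
    simulate_environment,
    simulate_expression,
    simulate_genotypes,
)


class TestGenotypes:
    def test_hwe_het_fraction(self):
        cfg = SimConfig(seed=2, n_samples=10_000, maf_reqtl=0.5)
        reqtl_hap, _ = simulate_genotypes(cfg)
        het = (reqtl_hap.sum(axis=1) == 1).mean()
        assert abs(het - 0.5) < 0.015

    def test_perfect_ld_identical(self):
        cfg = SimConfig(seed=3, n_samples=500, maf_reqtl=0.3, maf_tsnp=0.3, ld_r2=1.0)
        reqtl_hap, tsnp_hap = simulate_genotypes(cfg)
        np.testing.assert_array_equal(reqtl_hap, tsnp_hap[0])

    def test_ld_r2_approximately_achieved(self):
        cfg = SimConfig(seed=4, n_samples=20_000, maf_reqtl=0.4, maf_tsnp=0.4, ld_r2=0.5)
        reqtl_hap, tsnp_hap = simulate_genotypes(cfg)
        r = np.corrcoef(reqtl_hap.ravel(), tsnp_hap[0].ravel())[0, 1]
        assert abs(r**2 - 0.5) < 0.03

    def test_seeded_bit_identical(self):
        cfg = SimConfig(seed=5, n_samples=200, n_tsnps=3)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_infeasible_ld_reports_bound(self):
        cfg = SimConfig(seed=6, maf_reqtl=0.05, maf_tsnp=0.5, ld_r2=0.9)
        with pytest.raises(ValueError, match="must be <="):
            simulate_genotypes(cfg)


class TestAseCounts:
    def test_symmetric_null_alt_fraction(self):
        cfg = SimConfig(
            seed=7, n_samples=2000, n_tsnps=50, depth_mean=60,
            beta_seh=0.0, gamma_sh=0.0, mu_s=0.0,
        )
        gen = cfg.rng()
        rh, th = simulate_genotypes(cfg, gen)
        env = simulate_environment(cfg, gen)
        counts, _ = simulate_ase_counts(rh, th, env, cfg, gen)
        assert len(counts) > 1e5 * 0.4  # enough observations to average
        frac = counts["alt_count"] / (counts["ref_count"] + counts["alt_count"])
        assert abs(frac.mean() - 0.5) < 0.01

    def test_het_effect_increases_folded_imbalance(self):
        cfg = SimConfig(seed=8, n_samples=2000, n_tsnps=1, gamma_sh=1.0, mu_s=0.0)
        gen = cfg.rng()
        rh, th = simulate_genotypes(cfg, gen)
        env = simulate_environment(cfg, gen)
        counts, _ = simulate_ase_counts(rh, th, env, cfg, gen)
        tot = counts["ref_count"] + counts["alt_count"]
        imb = np.abs(0.5 - counts["alt_count"] / tot)
        het = counts["h"] == 1
        t = stats.mannwhitneyu(imb[het], imb[~het], alternative="greater")
        assert t.pvalue < 0.01

    def test_determinism(self):
        cfg = SimConfig(seed=9, n_samples=100, n_tsnps=2)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a["counts"], b["counts"])
        np.testing.assert_array_equal(a["expression"], b["expression"])

    def test_default_config_survives_qc(self):
        cfg = SimConfig(seed=10, n_samples=300, n_tsnps=20, depth_mean=60)
        data = simulate_dataset(cfg)
        counts = data["counts"]
        het = {(s, t): True for s, t in zip(counts["sample_id"], counts["tsnp_id"])}
        _, retained, _ = count_filters(counts, het)
        assert len(retained) / cfg.n_tsnps > 0.9

    def test_planted_signal_ranks_high(self, prior):
        # scaled down (8 seeds, 15 null tSNPs; spec sketch: 50 seeds):
        # the planted interaction must land in the top 5% (rank 1 of 16)
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = SimConfig(
                seed=11_000 + seed, n_samples=400, n_tsnps=16, mu_s=0.5,
                env_kind="dichotomous",
            )
            gen = cfg.rng()
            rh, th = simulate_genotypes(cfg, gen)
            env = simulate_environment(cfg, gen)
            null_counts, _ = simulate_ase_counts(rh, th, env, cfg, gen)
            # plant the signal at ts0 by regenerating it with beta_seh = 2
            from dataclasses import replace

            strong = replace(cfg, beta_seh=2.0, n_tsnps=1)
            planted, _ = simulate_ase_counts(rh, th[:1], env, strong, cfg.rng())
            counts = pd.concat(
                [planted, null_counts[null_counts["tsnp_id"] != "ts0"]], ignore_index=True
            )
            pvals = {}
            for t in counts["tsnp_id"].unique():
                full, _ = fit_ase_gxe(design_from_counts(counts, t), prior)
                pvals[t] = full.p_value
            best = min(pvals, key=pvals.get)
            hits += best == "ts0"
        assert hits >= n_seeds - 1


class TestExpression:
    def test_null_coverage(self):
        covered = 0
        for seed in range(100):
            cfg = SimConfig(seed=20_000 + seed, n_samples=200)
            gen = cfg.rng()
            rh, _ = simulate_genotypes(cfg, gen)
            env = simulate_environment(cfg, gen)
            y, Z, _ = simulate_expression(rh, env, cfg, gen)
            g = rh.sum(axis=1).astype(float)
            slope, _, _, p, _ = stats.linregress(g, y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0])
            covered += p > 0.05
        assert covered >= 94 - 8  # 94% nominal minus 3 binomial SD

    def test_power_at_cohort_size(self):
        rejects = 0
        for seed in range(200):
            cfg = SimConfig(seed=21_000 + seed, n_samples=267, maf_reqtl=0.3, beta_j=1.0)
            gen = cfg.rng()
            rh, _ = simulate_genotypes(cfg, gen)
            env = simulate_environment(cfg, gen)
            y, Z, _ = simulate_expression(rh, env, cfg, gen)
            spec = GeneModelSpec(Z=Z, e=env, g=rh.sum(axis=1).astype(float))
            rejects += fit_gene_interaction(y, spec).p_value <= 0.05
        assert rejects / 200 > 0.5

    def test_noiseless_identifiability(self):
        cfg = SimConfig(
            seed=22, n_samples=120, gamma_je=0.7, gamma_jg=-0.4, beta_j=1.3, noise_sd=0.0
        )
        gen = cfg.rng()
        rh, _ = simulate_genotypes(cfg, gen)
        env = simulate_environment(cfg, gen)
        y, Z, truth = simulate_expression(rh, env, cfg, gen)
        spec = GeneModelSpec(Z=Z, e=env, g=rh.sum(axis=1).astype(float))
        fit = fit_gene_interaction(y, spec)
        assert fit.beta == pytest.approx(1.3, abs=1e-8)
        assert fit.gamma_je == pytest.approx(0.7, abs=1e-8)
        assert fit.gamma_jg == pytest.approx(-0.4, abs=1e-8)


class TestCalibrationStudy:
    def test_null_cell_structure_and_rates(self):
        # small replicate count for the default suite; the acceptance test
        # runs the full-width null calibration
        cfg = SimConfig(seed=23, n_samples=200, mu_s=0.5, gamma_sh=0.2)
        out = calibration_study(cfg, n_reps=40)
        for arm in ("ase", "gene", "combined"):
            assert set(out["rejection"][arm]) == {0.05, 0.01}
            assert 0 <= out["rejection"][arm][0.05] <= 0.2
        assert out["qq_observed"]["ase"].shape == (40,)
        assert (np.diff(out["qq_observed"]["combined"]) >= 0).all()

    def test_fisher_combination_valid_under_independence(self):
        rng = np.random.default_rng(24)
        p = fisher_combine(rng.uniform(size=2000), rng.uniform(size=2000))
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestConfigValidation:
    def test_seed_mandatory(self):
        with pytest.raises(TypeError):
            SimConfig()

    def test_bad_maf(self):
        with pytest.raises(ValueError, match="maf"):
            SimConfig(seed=1, maf_reqtl=1.5)

    def test_bad_env_kind(self):
        with pytest.raises(ValueError, match="env_kind"):
            SimConfig(seed=1, env_kind="ordinal")
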