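import numpy as np
import pandas as pd
import pytest

from seqblup.errors import ConfigurationError, DataError
from seqblup.panels import GenotypeMatrix
from seqblup.simdata import (
    SimConfig,
    TraitConfig,
    corrupt_genotypes,
    hold_out_samples,
    simulate_genotypes,
    simulate_phenotypes,
)

from conftest import make_gm


class TestSimulateGenotypes:
    def test_shape_contract(self):
        cfg = SimConfig(n_individuals=2, n_snp=1, n_indel=0, block_size=1)
        gm, panel = simulate_genotypes(cfg)
        assert gm.dosage.shape == (2, 1)
        assert np.isin(gm.dosage, (0.0, 1.0, 2.0)).all()
        assert len(panel) == 1

    def test_maf_mean_matches_binomial_target(self):
        # fst=0, no missingness, every variant at alt frequency 0.3:
        # empirical MAF per variant is a binomial mean, so the average
        # over variants should sit tightly on 0.3
        cfg = SimConfig(
            n_individuals=2000, n_snp=300, fst=0.0, maf_range=(0.3, 0.3),
            within_block_corr=0.0, block_size=10, seed=5,
        )
        gm, _ = simulate_genotypes(cfg)
        assert abs(gm.maf().mean() - 0.3) < 0.02

    def test_within_block_r2_exceeds_between(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                n_individuals=1000, n_snp=60, block_size=10,
                within_block_corr=0.9, fst=0.0, seed=seed,
            )
            gm, _ = simulate_genotypes(cfg)
            r2 = np.corrcoef(gm.dosage, rowvar=False) ** 2
            blocks = np.arange(60) // 10
            same = blocks[:, None] == blocks[None, :]
            off = ~np.eye(60, dtype=bool)
            if r2[same & off].mean() > r2[~same].mean():
                hits += 1
        assert hits >= 19

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_individuals=50, n_snp=100, n_indel=20,
                        missing_rate=0.05, seed=9)
        gm1, _ = simulate_genotypes(cfg)
        gm2, _ = simulate_genotypes(cfg)
        np.testing.assert_array_equal(gm1.dosage, gm2.dosage)
        assert gm1.sample_ids == gm2.sample_ids
        pd.testing.assert_frame_equal(gm1.variants.table, gm2.variants.table)

    def test_subpop_labels_and_frequency_divergence(self):
        cfg = SimConfig(n_individuals=600, n_snp=400, fst=0.15, seed=3)
        gm, _ = simulate_genotypes(cfg)
        sub = gm.sample_info["subpop"].to_numpy()
        assert set(sub) == {"S1", "S2", "S3"}
        f1 = np.nanmean(gm.dosage[sub == "S1"], axis=0) / 2
        f2 = np.nanmean(gm.dosage[sub == "S2"], axis=0) / 2
        assert np.abs(f1 - f2).mean() > 0.05  # divergence driven by fst

    def test_maf_spectrum_ks(self):
        from scipy.stats import kstest

        cfg = SimConfig(
            n_individuals=1500, n_snp=10_000, fst=0.0,
            maf_range=(0.05, 0.5), within_block_corr=0.0, seed=2,
        )
        gm, _ = simulate_genotypes(cfg)
        stat = kstest(gm.maf(), "uniform", args=(0.05, 0.45)).statistic
        assert stat < 0.05

    def test_block_size_too_large_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_individuals=10, n_snp=5, block_size=10)

    def test_indel_count(self):
        cfg = SimConfig(n_individuals=20, n_snp=80, n_indel=20, seed=1)
        gm, panel = simulate_genotypes(cfg)
        assert panel.type_counts() == {"SNP": 80, "INDEL": 20}


class TestSimulatePhenotypes:
    def _sim(self, n=500, h2_snp=0.3, h2_indel=0.0, seed=1, **kw):
        cfg = SimConfig(n_individuals=n, n_snp=400, n_indel=100, seed=seed)
        gm, panel = simulate_genotypes(cfg)
        tc = TraitConfig(
            h2_snp=h2_snp, h2_indel=h2_indel,
            n_causal_snp=kw.pop("n_causal_snp", 80),
            n_causal_indel=kw.pop("n_causal_indel", 20 if h2_indel else 0),
            seed=seed + 1, **kw,
        )
        pt, truth = simulate_phenotypes(gm, panel, tc)
        return gm, pt, truth

    def test_null_heritability_gives_zero_bv(self):
        _, _, truth = self._sim(h2_snp=0.0, h2_indel=0.0)
        assert truth.true_breeding_values["bv_total"].var() == 0.0

    def test_variance_ratio_hits_target(self):
        cfg = SimConfig(n_individuals=2000, n_snp=800, n_indel=0, seed=4)
        gm, panel = simulate_genotypes(cfg)
        tc = TraitConfig(h2_snp=0.3, n_causal_snp=150, seed=5)
        pt, truth = simulate_phenotypes(gm, panel, tc)
        y = pt.trait_values("trait")
        fixed = np.zeros(len(y))
        for factor, effects in truth.fixed_effect_values.items():
            lv = pt.data[factor].str.removeprefix(factor).astype(int) - 1
            fixed += np.asarray(effects)[lv]
        bv = truth.true_breeding_values["bv_snp"].to_numpy()
        ratio = bv.var() / (y - fixed).var()
        assert 0.25 <= ratio <= 0.35

    def test_identical_genotypes_identical_bv(self):
        cfg = SimConfig(n_individuals=10, n_snp=50, seed=8)
        gm, _ = simulate_genotypes(cfg)
        dup = np.vstack([gm.dosage, gm.dosage[:1]])
        gm2 = GenotypeMatrix(
            gm.sample_ids + ["clone"], gm.variants, dup
        )
        tc = TraitConfig(h2_snp=0.5, n_causal_snp=20, seed=2)
        _, truth = simulate_phenotypes(gm2, gm2.variants, tc)
        bv = truth.true_breeding_values["bv_total"].to_numpy()
        assert bv[-1] == bv[0]

    def test_deterministic(self):
        _, pt1, _ = self._sim(seed=6)
        _, pt2, _ = self._sim(seed=6)
        pd.testing.assert_frame_equal(pt1.data, pt2.data)

    def test_h2_sum_rejected(self):
        with pytest.raises(ConfigurationError):
            TraitConfig(h2_snp=0.6, h2_indel=0.4)

    @pytest.mark.parametrize("n,tol", [(200, 0.15), (2000, 0.05)])
    def test_realized_h2_converges(self, n, tol):
        _, _, truth = self._sim(n=n, h2_snp=0.3, seed=12)
        assert abs(truth.true_h2["snp"] - 0.3) < tol


class TestCorruptGenotypes:
    def test_zero_rate_identity(self, sim_gm):
        out = corrupt_genotypes(sim_gm, 0.0, seed=1)
        np.testing.assert_array_equal(out.dosage, sim_gm.dosage)

    def test_full_corruption_hwe_concordance(self, rng):
        # truth at p=0.5, replacement drawn from HWE(0.5): expected
        # agreement = sum of squared genotype frequencies = 0.375
        gm = make_gm(rng.binomial(2, 0.5, size=(10_000, 8)).astype(float))
        out = corrupt_genotypes(gm, 1.0, seed=3)
        agree = (out.dosage == gm.dosage).mean()
        assert abs(agree - 0.375) < 0.015

    def test_deterministic(self, sim_gm):
        a = corrupt_genotypes(sim_gm, 0.3, seed=7)
        b = corrupt_genotypes(sim_gm, 0.3, seed=7)
        np.testing.assert_array_equal(a.dosage, b.dosage)

    def test_missing_stays_missing(self, sim_gm):
        out = corrupt_genotypes(sim_gm, 0.5, seed=2)
        np.testing.assert_array_equal(
            np.isnan(out.dosage), np.isnan(sim_gm.dosage)
        )

    def test_maf_weighted_targets_high_maf(self, rng):
        p = np.concatenate([np.full(30, 0.05), np.full(30, 0.45)])
        gm = make_gm(rng.binomial(2, p, size=(2000, 60)).astype(float))
        out = corrupt_genotypes(gm, 0.2, mode="maf_weighted", seed=5)
        changed = (out.dosage != gm.dosage).mean(axis=0)
        assert changed[30:].mean() > changed[:30].mean()

    def test_bad_rate_rejected(self, sim_gm):
        with pytest.raises(ConfigurationError):
            corrupt_genotypes(sim_gm, 1.5)


class TestHoldOut:
    def test_population_scale_count(self):
        gm = make_gm(np.zeros((1469, 1)))
        held, kept = hold_out_samples(gm, 0.2, seed=1)
        assert len(held) == 294

    def test_small_count(self):
        gm = make_gm(np.zeros((10, 1)))
        held, _ = hold_out_samples(gm, 0.2, seed=1)
        assert len(held) == 2

    def test_partition(self, sim_gm):
        held, kept = hold_out_samples(sim_gm, 0.2, seed=9)
        assert set(held) | set(kept) == set(sim_gm.sample_ids)
        assert not set(held) & set(kept)

    def test_tiny_population_rejected(self):
        gm = make_gm(np.zeros((1, 1)))
        with pytest.raises(DataError):
            hold_out_samples(gm, 0.5)

    def test_deterministic(self, sim_gm):
        assert hold_out_samples(sim_gm, 0.2, seed=4) == hold_out_samples(
            sim_gm, 0.2, seed=4
        )
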