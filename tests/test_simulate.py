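"""Generators: fish-bone block design and lifespan cohorts with ground truth."""

import numpy as np
import pandas as pd
import pytest

import atrophytwin as at
from atrophytwin.simulate import fishbone_true_mean


class TestFishbone:
    def test_default_training_counts(self):
        table = at.generate_fishbone_training(at.FishboneConfig(), seed=0)
        assert table.n_subjects == 500
        assert table.n_scans == 2500
        assert (table.scan_counts() == 5).all()

    def test_default_testing_counts_and_extrapolation_ages(self):
        table = at.generate_fishbone_testing(at.FishboneConfig(), seed=0)
        assert table.n_subjects == 50
        assert table.n_scans == 50 * 54
        ages = set(table.scans["age_at_scan"])
        assert {26.0, 27.0, 28.0, 29.0} <= ages
        assert (table.scan_counts() == 54).all()

    def test_same_seed_identical(self):
        a = at.generate_fishbone_training(at.FishboneConfig(subjects_per_block=5), 3)
        b = at.generate_fishbone_training(at.FishboneConfig(subjects_per_block=5), 3)
        pd.testing.assert_frame_equal(a.scans, b.scans)
        t1 = at.generate_fishbone_testing(at.FishboneConfig(n_test_subjects=4), 3)
        t2 = at.generate_fishbone_testing(at.FishboneConfig(n_test_subjects=4), 3)
        pd.testing.assert_frame_equal(t1.scans, t2.scans)

    def test_zero_noise_lies_on_fixed_effect_lines(self):
        cfg = at.FishboneConfig(subjects_per_block=4, sigma=0.0,
                                intercept_sd=0.0, slope_sd=0.0)
        table = at.generate_fishbone_training(cfg, seed=1)
        s = table.scans
        block = ((s["age_at_scan"] - cfg.age_start) // cfg.block_width).astype(int)
        year = s["age_at_scan"] - cfg.age_start - cfg.block_width * block
        is_ms = (s["group"] == "MS").astype(float)
        expect = [fishbone_true_mean(cfg, k, y, m)
                  for k, y, m in zip(block, year, is_ms)]
        np.testing.assert_allclose(s["norm_thalamus"], expect, atol=1e-9)

    def test_mean_at_year_zero_matches_analytic_expectation(self):
        # E[Y | Year=0, block k] = W_k*b00 + b01*MS; Monte Carlo over many subjects
        cfg = at.FishboneConfig(subjects_per_block=800, n_blocks=10)
        table = at.generate_fishbone_training(cfg, seed=5)
        W, _ = cfg.weights()
        s = table.scans
        block = ((s["age_at_scan"] - cfg.age_start) // cfg.block_width).astype(int)
        year0 = s[(s["age_at_scan"] % cfg.block_width) == 0]
        for k in (0, 4, 9):
            sub = year0[block[year0.index] == k]
            for grp, shift in (("control", 0.0), ("MS", cfg.beta01)):
                vals = sub.loc[sub["group"] == grp, "norm_thalamus"]
                mc_se = np.sqrt(cfg.intercept_sd**2 + cfg.sigma**2) / np.sqrt(len(vals))
                assert abs(vals.mean() - (W[k] * cfg.beta00 + shift)) < 3 * mc_se

    def test_weight_schedule_monotone_and_three_phase(self):
        cfg = at.FishboneConfig()
        W, V = cfg.weights()
        assert len(W) == cfg.n_blocks and np.array_equal(W, V)
        steps = 1.0 - W[1:] / W[:-1]
        np.testing.assert_allclose(steps * 100,
                                   [1, 1, 1, 5, 5, 5, 1, 1, 1], atol=1e-9)
        assert (np.diff(W) <= 0).all()

    def test_non_psd_random_effects_rejected(self):
        cfg = at.FishboneConfig(re_corr=1.5)
        with pytest.raises(ValueError, match="PSD"):
            at.generate_fishbone_training(cfg, 0)

    def test_training_residual_normality(self):
        # subtract known fixed part; remaining = b0 + b1*Year + eps is Gaussian
        from scipy import stats
        cfg = at.FishboneConfig(subjects_per_block=50)
        table = at.generate_fishbone_training(cfg, seed=9)
        s = table.scans
        block = ((s["age_at_scan"] - cfg.age_start) // cfg.block_width).astype(int)
        year = s["age_at_scan"] - cfg.age_start - cfg.block_width * block
        is_ms = (s["group"] == "MS").astype(float)
        fixed = np.array([fishbone_true_mean(cfg, k, y, m)
                          for k, y, m in zip(block, year, is_ms)])
        resid = s["norm_thalamus"].to_numpy() - fixed
        # normality of the marginal residual (a Gaussian mixture of Gaussians
        # is Gaussian here since all components are linear in Gaussians)
        assert stats.normaltest(resid).pvalue > 1e-4


class TestLifespan:
    def test_counts_match_config(self):
        cfg = at.LifespanConfig(n_controls=120, n_ms=40)
        table, truth = at.generate_lifespan_cohort(cfg, 2)
        groups = table.covariates.groupby("group").size()
        assert groups["control"] == 120 and groups["MS"] == 40
        assert len(truth.subjects) == 160

    def test_same_seed_identical(self):
        cfg = at.LifespanConfig(n_controls=50, n_ms=20)
        a, _ = at.generate_lifespan_cohort(cfg, 4)
        b, _ = at.generate_lifespan_cohort(cfg, 4)
        pd.testing.assert_frame_equal(a.scans, b.scans)

    def test_ms_scan_counts_cluster_around_four(self, lifespan_small):
        _, table, _ = lifespan_small
        counts = table.ms().scan_counts()
        assert 2 <= counts.min() and counts.max() <= 8
        assert 3.0 < counts.mean() < 5.0

    def test_null_ms_effect_indistinguishable_from_controls(self):
        # excess rate 0: MS scan residuals around f0 have mean ~ 0
        from scipy import stats
        ps = []
        for seed in range(6):
            cfg = at.LifespanConfig(n_controls=30, n_ms=80, excess_rate=0.0)
            table, truth = at.generate_lifespan_cohort(cfg, seed)
            sc = table.ms().scans.merge(truth.subjects, on="subject_id")
            resid = sc["norm_thalamus"] - cfg.f0(sc["age_at_scan"], sc["female"], sc["icv_z"])
            ps.append(stats.ttest_1samp(resid, 0.0).pvalue)
        assert min(ps) > 0.01 / len(ps)  # no seed flags a group effect

    def test_deviation_age_never_after_clinical_onset(self):
        cfg = at.LifespanConfig(n_controls=10, n_ms=200)
        table, truth = at.generate_lifespan_cohort(cfg, 3)
        merged = truth.subjects.merge(table.covariates, on="subject_id")
        ms = merged[merged["group_x"] == "MS"]
        assert (ms["a0"] <= ms["clinical_onset_age"] + 1e-9).all()

    def test_ms_truth_never_exceeds_control_twin(self, lifespan_small):
        cfg, table, truth = lifespan_small
        ages = np.linspace(16, 90, 50)
        ms = truth.subjects[truth.subjects["group"] == "MS"].iloc[0]
        with_ms = at.eval_true_mean(cfg, "MS", ages, female=ms["female"],
                                    icv_z=ms["icv_z"], a0=ms["a0"])
        without = at.eval_true_mean(cfg, "control", ages, female=ms["female"],
                                    icv_z=ms["icv_z"])
        assert (with_ms <= without + 1e-12).all()


class TestTrueMean:
    def test_control_is_f0(self):
        cfg = at.LifespanConfig()
        assert at.eval_true_mean(cfg, "control", 40.0, female=1.0, icv_z=0.0) == \
            pytest.approx(cfg.f0(40.0, 1.0, 0.0))

    def test_continuity_at_deviation_age(self):
        cfg = at.LifespanConfig()
        lo = at.eval_true_mean(cfg, "MS", 28.0 - 1e-9, female=0.0, icv_z=0.0, a0=28.0)
        hi = at.eval_true_mean(cfg, "MS", 28.0 + 1e-9, female=0.0, icv_z=0.0, a0=28.0)
        ctrl = at.eval_true_mean(cfg, "control", 28.0, female=0.0, icv_z=0.0)
        assert lo == pytest.approx(ctrl, abs=1e-6)
        assert hi == pytest.approx(ctrl, abs=1e-6)

    @pytest.mark.parametrize("shape", ["linear", "quadratic"])
    def test_excess_matches_quadrature_of_rate(self, shape):
        # accumulated loss equals the integral of the instantaneous rate
        from scipy.integrate import quad
        cfg = at.LifespanConfig(excess_shape=shape)
        a0, r, ramp = 28.0, cfg.excess_rate, 4.0

        def rate(t):
            if shape == "linear":
                return r if t > a0 else 0.0
            return r * min(max(t - a0, 0.0) / ramp, 1.0)

        for age in (30.0, 38.0, 55.0):
            expected, _ = quad(rate, 15.0, age, points=[a0, a0 + ramp])
            got = cfg.excess(age, a0)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_age_outside_support_rejected(self):
        with pytest.raises(ValueError):
            at.eval_true_mean(at.LifespanConfig(), "control", 10.0)
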