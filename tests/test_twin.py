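"""Twin trajectories, PBTL onset detection, bootstrap CIs, gap summaries."""

import numpy as np
import pandas as pd
import pytest

import atrophytwin as at
from atrophytwin.bases import SplineSpec
from atrophytwin.mixed import CovariateStructure
from atrophytwin.twin import (
    DEFAULT_GRID,
    OnsetBootstrapper,
    OnsetEstimate,
    TrajectoryPair,
    _resample_table,
    summarize_gaps,
    twin_profile,
)


def make_pair(ages, d, level=9.0):
    """TrajectoryPair with twin - ms == d and flat bands."""
    ages = np.asarray(ages, dtype=float)
    twin = np.full_like(ages, level)
    ms = twin - d
    z = np.zeros_like(ages)
    return TrajectoryPair(ages, ms, ms - 0.1, ms + 0.1, twin, twin - 0.1,
                          twin + 0.1, {"subject_id": "p", "onset_age": 36.0})


class TestBuildPair:
    def test_grid_length_61(self, small_fit):
        pat = dict(subject_id="x", sex="F", thalamus0=9.5, icv0=1.45e6,
                   onset_age=30.0, dmt0=1.0, entry_age=40.0)
        pair = at.build_twin_pair(small_fit, pat)
        assert len(pair.ages) == 61
        assert pair.ages[0] == 15.0 and pair.ages[-1] == 75.0

    def test_twin_zeroes_disease_covariates(self):
        prof = twin_profile(dict(sex="F", onset_age=31.0, dmt0=2.5,
                                 thalamus0=9.1, icv0=1.4e6, entry_age=40.0))
        assert prof["onset_age"] == 0.0 and prof["dmt0"] == 0.0
        assert prof["thalamus0"] == 9.1

    def test_null_model_gives_identical_curves(self, small_fit):
        # zero out every MS-specific coefficient: curves must coincide
        import copy
        fit = copy.copy(small_fit)
        fit.fe_params = small_fit.fe_params.copy()
        fit.blups = small_fit.blups.copy()
        for i, name in enumerate(fit.model.fixed_names):
            if "MS" in name:
                fit.fe_params[i] = 0.0
        k = fit.model.basis.n_penalized
        pos = 0
        for name in fit.model.penalized_blocks:
            width = fit.model.n_pen // len(fit.model.penalized_blocks)
            if "MS" in name:
                fit.blups[pos:pos + width] = 0.0
            pos += width
        pat = dict(sex="F", thalamus0=9.5, icv0=1.45e6, onset_age=30.0,
                   dmt0=0.0, entry_age=40.0)
        pair = at.build_twin_pair(fit, pat)
        np.testing.assert_allclose(pair.ms, pair.twin, atol=1e-10)
        det = at.detect_pbtl_onset(pair)
        assert det.undetermined


class TestDetect:
    def test_constructed_crossing_at_30(self):
        ages = np.arange(15.0, 76.0)
        d = np.where(ages <= 30, 0.0, 0.1 * (ages - 30))
        det = at.detect_pbtl_onset(make_pair(ages, d))
        assert det.age == pytest.approx(30.0, abs=1e-9)
        assert not det.no_crossing

    def test_hinge_crossing_interpolated(self):
        ages = np.arange(15.0, 76.0)
        d = np.maximum(0.0, ages - 42.0) * 0.05
        det = at.detect_pbtl_onset(make_pair(ages, d))
        assert det.age == pytest.approx(42.0, abs=0.1)

    def test_shift_equivariance(self):
        ages = np.arange(15.0, 76.0)
        d = np.maximum(0.0, ages - 33.0) * 0.02
        p1 = make_pair(ages, d, level=9.0)
        p2 = make_pair(ages, d, level=11.5)  # both curves shifted equally
        assert at.detect_pbtl_onset(p1).age == at.detect_pbtl_onset(p2).age

    def test_identical_curves_undetermined(self):
        ages = np.arange(15.0, 76.0)
        det = at.detect_pbtl_onset(make_pair(ages, np.zeros_like(ages)))
        assert det.undetermined and np.isnan(det.age)

    def test_never_crossing_flag_and_argmin(self):
        ages = np.arange(15.0, 76.0)
        d = 0.5 + 0.01 * (ages - 15)  # always departed
        det = at.detect_pbtl_onset(make_pair(ages, d))
        assert det.no_crossing
        assert det.age == 15.0


class TestClassify:
    def make_estimate(self, ci_high, onset, ci_low=20.0):
        return OnsetEstimate("p", (ci_low + ci_high) / 2, ci_low, ci_high,
                             onset, 0.0, "", 100, 0.0)

    def test_upper_limit_below_onset_is_earlier(self):
        assert at.classify_onset(self.make_estimate(33.0, 36.0)) == "earlier"

    def test_interval_containing_onset_is_simultaneous(self):
        assert at.classify_onset(self.make_estimate(45.0, 30.0)) == "simultaneous"

    def test_tie_is_simultaneous(self):
        assert at.classify_onset(self.make_estimate(36.0, 36.0)) == "simultaneous"

    def test_controls_rejected(self):
        with pytest.raises(ValueError):
            at.classify_onset(self.make_estimate(30.0, 0.0))


class TestBootstrap:
    def test_resampled_tables_move_whole_blocks(self, lifespan_small):
        _, table, _ = lifespan_small
        counts = table.scan_counts()
        ids = table.subject_ids()
        rng = np.random.default_rng(0)
        take = ids[rng.integers(0, len(ids), len(ids))]
        rep = _resample_table(table, take)
        rep_counts = rep.scan_counts()
        for k, sid in enumerate(take):
            assert rep_counts[f"B{k:05d}"] == counts[sid]
        assert rep.n_scans == sum(counts[s] for s in take)

    def test_identical_replicates_give_zero_width_ci(self, small_fit):
        boot = OnsetBootstrapper.__new__(OnsetBootstrapper)
        boot.base = small_fit
        boot.model = small_fit.model
        boot.B = 2
        boot.mode = "fast"
        boot.n_failed = 0
        coef = np.concatenate([small_fit.fe_params, small_fit.blups])
        boot.coefs = np.vstack([coef, coef])
        pat = dict(subject_id="p", sex="F", thalamus0=9.5, icv0=1.45e6,
                   onset_age=34.0, dmt0=0.0, entry_age=42.0)
        est = boot.estimate(pat)
        assert est.ci_low == pytest.approx(est.ci_high)
        assert est.pbtl_age == pytest.approx(est.ci_low)

    def test_fast_mode_close_to_refit_mode(self, small_fit):
        pat = dict(subject_id="p", sex="F", thalamus0=9.5, icv0=1.45e6,
                   onset_age=34.0, dmt0=0.0, entry_age=42.0)
        fast = OnsetBootstrapper(small_fit, B=40, seed=5, mode="fast").estimate(pat)
        refit = OnsetBootstrapper(small_fit, B=40, seed=5, mode="refit").estimate(pat)
        assert fast.n_boot_effective > 0 and refit.n_boot_effective > 0
        # the two CI constructions agree on the broad location
        assert abs(fast.pbtl_age - refit.pbtl_age) < 10.0

    def test_patient_in_training_table_rejected(self, lifespan_small):
        _, table, _ = lifespan_small
        sid = table.ms().subject_ids()[0]
        pat = table.covariates.set_index("subject_id", drop=False).loc[sid]
        with pytest.raises(ValueError, match="training"):
            at.bootstrap_onset_ci(table, SplineSpec("cubic_bspline", "toep1", 8),
                                  at.mandatory_structure(), pat, B=2, seed=0)

    def test_b_validation(self, small_fit):
        with pytest.raises(ValueError):
            OnsetBootstrapper(small_fit, B=1)


class TestTenfold:
    @pytest.fixture(scope="class")
    def onsets(self, lifespan_small):
        _, table, _ = lifespan_small
        struct = CovariateStructure("s", (("sex", frozenset({"main", "ms"})),))
        return at.run_tenfold(table, SplineSpec("cubic_bspline", "toep1", 10),
                              struct, B=50, seed=3, mode="fast")

    def test_every_ms_subject_estimated_once(self, onsets, lifespan_small):
        _, table, _ = lifespan_small
        assert sorted(onsets["subject_id"]) == sorted(table.ms().subject_ids())
        assert onsets["subject_id"].is_unique

    def test_folds_disjoint_and_balanced(self, onsets):
        sizes = onsets.groupby("fold").size()
        assert len(sizes) == 10
        assert sizes.max() - sizes.min() <= 1

    def test_same_seed_reproducible(self, onsets, lifespan_small):
        _, table, _ = lifespan_small
        struct = CovariateStructure("s", (("sex", frozenset({"main", "ms"})),))
        again = at.run_tenfold(table, SplineSpec("cubic_bspline", "toep1", 10),
                               struct, B=50, seed=3, mode="fast")
        pd.testing.assert_frame_equal(onsets, again)

    def test_summary_statistics(self, onsets):
        summary = summarize_gaps(onsets)
        assert summary.n == len(onsets.dropna(subset=["pbtl_age"]))
        assert 0.0 <= summary.prop_earlier <= 1.0
        assert "gap" in summary.summary()


class TestGapSummary:
    def frame(self, pbtl, onset, label):
        return pd.DataFrame(
            dict(subject_id=[f"p{i}" for i in range(len(pbtl))],
                 pbtl_age=pbtl, ci_low=np.array(pbtl) - 2,
                 ci_high=np.array(pbtl) + 2, clinical_onset=onset,
                 gap=np.array(pbtl) - np.array(onset), label=label,
                 n_boot_effective=100, no_crossing_rate=0.0, flagged=False))

    def test_constant_gap_degenerate_limits(self):
        df = self.frame([25.0, 30.0, 35.0], [30.0, 35.0, 40.0],
                        ["earlier"] * 3)
        s = summarize_gaps(df)
        assert s.mean_gap == pytest.approx(5.0)
        assert s.sd_gap == pytest.approx(0.0)
        ba = s.bland_altman_all
        assert ba.loa_low == pytest.approx(-5.0)
        assert ba.loa_high == pytest.approx(-5.0)

    def test_hand_bland_altman(self):
        # differences 1, 2, 3 -> mean 2, sd 1, limits (0.04, 3.96)
        ba = at.bland_altman([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert ba.mean_diff == pytest.approx(2.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(0.04)
        assert ba.loa_high == pytest.approx(3.96)

    def test_too_few_estimates_rejected(self):
        with pytest.raises(ValueError):
            summarize_gaps(self.frame([25.0], [30.0], ["earlier"]))
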