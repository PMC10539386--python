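"""Penalized spline mixed model: design assembly, likelihood, oracles, bands."""

import json

import numpy as np
import pytest

import atrophytwin as at
from atrophytwin.bases import SplineSpec
from atrophytwin.cohort import build_scan_table
from atrophytwin.mixed import CovariateStructure, MixedSplineModel
from atrophytwin.selection import final_paper_structure
from conftest import make_scan_frame


def spec(basis="cubic_bspline", penalty="toep1", k=10):
    return SplineSpec(basis, penalty, k)


class TestDesignAssembly:
    def test_mandatory_fixed_columns_full_duplication(self, lifespan_small):
        _, table, _ = lifespan_small
        m = MixedSplineModel(table, spec("cubic_tpf"), ms_poly="full")
        expect = ["intercept", "age^1", "age^2", "age^3",
                  "MS", "MS:age^1", "MS:age^2", "MS:age^3"]
        assert m.fixed_names == expect
        assert m.penalized_blocks[:2] == ["smooth", "smooth:MS"]

    def test_default_linear_interaction_trend(self, lifespan_small):
        _, table, _ = lifespan_small
        m = MixedSplineModel(table, spec("cubic_tpf"))
        assert m.fixed_names == ["intercept", "age^1", "age^2", "age^3", "MS", "MS:age^1"]

    def test_sex_main_effect_adds_one_column(self, lifespan_small):
        _, table, _ = lifespan_small
        base = MixedSplineModel(table, spec())
        plus = MixedSplineModel(
            table, spec(),
            CovariateStructure("s", (("sex", frozenset({"main"})),)))
        assert plus.n_fixed == base.n_fixed + 1
        assert plus.fixed_names[-1] == "sex"

    def test_final_structure_assembles_and_fits(self, lifespan_small):
        _, table, _ = lifespan_small
        fit = MixedSplineModel(table, spec(), final_paper_structure()).fit("ML")
        assert fit.converged
        assert np.isfinite(fit.aic)
        names = fit.model.fixed_names
        for required in ("sex", "sex:MS", "sex:age^1", "thalamus0", "icv0",
                         "onset_age", "dmt0", "entry_age"):
            assert required in names

    def test_missing_covariate_rejected_in_prediction(self, small_fit):
        with pytest.raises(ValueError, match="missing covariate"):
            small_fit.predict({"thalamus0": 9.0}, "MS", np.arange(20.0, 30.0))

    def test_unknown_group_rejected(self, small_fit):
        with pytest.raises(ValueError, match="group"):
            small_fit.predict({"sex": "F"}, "healthy", np.arange(20.0, 30.0))


def simulate_from_design(model, beta, tau, sig_b, sigma, rng):
    """Draw a response vector from the model's own design (oracle generator)."""
    u = rng.normal(0.0, tau, model.n_pen)
    b = rng.normal(0.0, sig_b, model.n_subjects)
    subj = np.repeat(b, model._counts)
    return model.X @ beta + model.Z @ u + subj + rng.normal(0.0, sigma, model.n_obs)


class TestLikelihood:
    def test_gls_oracle_fixed_components(self):
        # 50 subjects, components fixed at truth: fixed effects must equal
        # the closed-form dense GLS solution
        cfg = at.LifespanConfig(n_controls=35, n_ms=15)
        table, _ = at.generate_lifespan_cohort(cfg, 21)
        model = MixedSplineModel(table, spec(k=8))
        lam_s, lam_b = 0.7, 2.0
        fit = model.fit("ML", fixed_components=(lam_s, lam_b))

        n = model.n_obs
        V = np.eye(n) + lam_s * (model.Z @ model.Z.T)
        pos = 0
        for c in model._counts:
            V[pos:pos + c, pos:pos + c] += lam_b
            pos += c
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(model.X.T @ Vi @ model.X, model.X.T @ Vi @ model.y)
        np.testing.assert_allclose(fit.fe_params, beta, atol=1e-8)

    def test_unpenalized_limit_interpolates_cubic(self):
        # noise-free cubic truth, huge smoothing variance, no subject noise:
        # the fit reproduces the generating cubic essentially exactly
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 80, 120)
        vals = 11.0 - 0.01 * ages + 1e-4 * (ages - 50) ** 2 - 2e-6 * (ages - 50) ** 3
        rows = [(f"s{i}", "control", "F", a, 1e6, v * 1e6 / 1000.0, 0.0, 0.0)
                for i, (a, v) in enumerate(zip(ages, vals))]
        table = build_scan_table(make_scan_frame(rows))
        model = MixedSplineModel(table, spec("cubic_tpf", k=6))
        fit = model.fit("ML", fixed_components=(1e8, 1e-8))
        np.testing.assert_allclose(fit.fitted_values(), model.y, atol=1e-6)

    def test_zero_penalty_limit_matches_statsmodels_mixedlm(self):
        # lam_s -> 0 collapses the model to a cubic polynomial + random
        # intercept LMM; cross-check fixed effects against statsmodels at the
        # same variance ratio
        import statsmodels.api as sm

        cfg = at.LifespanConfig(n_controls=80, n_ms=0, control_repeat_fraction=0.6)
        table, _ = at.generate_lifespan_cohort(cfg, 5)
        model = MixedSplineModel(table, spec("cubic_tpf", k=6))
        s = (table.scans["age_at_scan"] - model.basis.a_min) / \
            (model.basis.a_max - model.basis.a_min)
        X = np.vander(s.to_numpy(), 4, increasing=True)
        groups = table.scans["subject_id"].to_numpy()
        lm = sm.MixedLM(table.scans["norm_thalamus"].to_numpy(), X, groups=groups)
        res = lm.fit(reml=True, method="lbfgs")
        ratio = float(np.asarray(res.cov_re)[0, 0] / res.scale)
        ours = model.fit("REML", fixed_components=(1e-12, ratio))
        np.testing.assert_allclose(ours.fe_params[:4], res.fe_params, atol=1e-5)

    def test_reml_recovers_variance_components(self):
        # simulate from the model's own design; REML estimates of the residual
        # and subject variances are nearly unbiased on average
        cfg = at.LifespanConfig(n_controls=350, n_ms=150)
        table, _ = at.generate_lifespan_cohort(cfg, 17)
        model = MixedSplineModel(table, spec(k=8))
        rng = np.random.default_rng(99)
        beta = rng.normal(0, 0.3, model.n_fixed)
        beta[0] = 9.5
        tau, sig_b, sigma = 0.1, 0.6, 0.3
        est = []
        y0 = model.y
        for _ in range(40):
            model.y = simulate_from_design(model, beta, tau, sig_b, sigma, rng)
            model._precompute()
            fit = model.fit("REML")
            est.append((fit.sigma2, fit.subject_var[0]))
        model.y = y0
        model._precompute()
        est = np.array(est)
        assert abs(est[:, 0].mean() / sigma**2 - 1) < 0.10
        assert abs(est[:, 1].mean() / sig_b**2 - 1) < 0.10

    def test_natural_bases_equivalent_likelihood(self, fishbone_small):
        _, table = fishbone_small
        m1 = MixedSplineModel(table, spec("natural_tpf"))
        m2 = MixedSplineModel(table, spec("natural_bspline"), knots=m1.basis.knots)
        f1, f2 = m1.fit("ML"), m2.fit("ML")
        assert abs(f1.aic - f2.aic) < 1e-3
        np.testing.assert_allclose(f1.fitted_values(), f2.fitted_values(), atol=1e-6)

    def test_invalid_method(self, lifespan_small):
        _, table, _ = lifespan_small
        with pytest.raises(ValueError):
            MixedSplineModel(table, spec()).fit("MAP")


class TestPrediction:
    def test_band_wider_under_extrapolation(self, small_fit):
        pat = dict(sex="F", thalamus0=9.5, icv0=1.45e6, onset_age=0.0,
                   dmt0=0.0, entry_age=40.0)
        curve, lo, hi = small_fit.predict(pat, "control", np.array([15.0, 45.0]))
        half = (hi - lo) / 2
        assert half[0] > half[1]

    def test_population_curves_identical_for_level_shift_covariates(self, lifespan_small):
        # thalamus0 enters as a main effect only: twin and MS curves shift by
        # the same amount, so their difference is invariant
        _, table, _ = lifespan_small
        structure = CovariateStructure("t0", (("thalamus0", frozenset({"main"})),))
        fit = MixedSplineModel(table, spec(), structure).fit("ML")
        ages = np.arange(15.0, 76.0)
        base = dict(sex="F", thalamus0=9.0, icv0=1.45e6, onset_age=30.0,
                    dmt0=0.0, entry_age=40.0)
        high = dict(base, thalamus0=10.5)
        d_base = (fit.predict(base, "control", ages, band=False)[0]
                  - fit.predict(base, "MS", ages, band=False)[0])
        d_high = (fit.predict(high, "control", ages, band=False)[0]
                  - fit.predict(high, "MS", ages, band=False)[0])
        np.testing.assert_allclose(d_base, d_high, atol=1e-8)

    def test_null_simulation_difference_within_band(self):
        # no MS effect: the MS-minus-control population difference stays
        # within its own 95% band at nearly all grid points
        cfg = at.LifespanConfig(n_controls=250, n_ms=120, excess_rate=0.0)
        table, _ = at.generate_lifespan_cohort(cfg, 23)
        structure = CovariateStructure("s", (("sex", frozenset({"main", "ms"})),))
        fit = MixedSplineModel(table, spec(k=10), structure).fit("ML")
        ages = np.arange(18.0, 71.0)
        pat = dict(sex="F", thalamus0=9.5, icv0=1.45e6, onset_age=0.0,
                   dmt0=0.0, entry_age=40.0)
        Xm, Zm = fit.model.design_rows(pat, "MS", ages)
        Xc, Zc = fit.model.design_rows(pat, "control", ages)
        R = np.column_stack([Xm - Xc, Zm - Zc])
        coefs = np.concatenate([fit.fe_params, fit.blups])
        d = R @ coefs
        var = np.einsum("ij,jk,ik->i", R, fit.cov_joint, R)
        inside = np.abs(d) <= 1.96 * np.sqrt(var) + 1e-12
        assert inside.mean() >= 0.9

    def test_predict_scans_matches_population_fit(self, small_fit):
        table = small_fit.model.table
        pred = small_fit.predict_scans(table)
        assert len(pred) == table.n_scans
        assert np.isfinite(pred).all()
        resid = table.scans["norm_thalamus"].to_numpy() - pred
        assert np.abs(resid).mean() < 1.0  # population-level, subject effects off


def test_results_serialization(small_fit):
    payload = json.loads(small_fit.to_json())
    assert payload["spec"]["basis"] == "cubic_bspline"
    assert payload["variance"]["sigma2"] > 0
    assert len(payload["blups"]) == small_fit.model.n_pen
    assert "MS" in payload["fe_params"]


def test_summary_mentions_key_quantities(small_fit):
    text = small_fit.summary()
    assert "AIC" in text and "sigma^2" in text and "MS" in text
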