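"""Reproducible end-to-end experiments exercising the whole pipeline.

Each function regenerates its synthetic inputs from a seed, runs the relevant
part of the pipeline at a stated problem size, and returns plain-float
summaries.  They back both the acceptance test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .augment import augment_cohort, validate_augmentation
from .bases import SplineSpec
from .cohort import ScanTable
from .mars import fit_adaptive_spline
from .mixed import CovariateStructure, MixedSplineModel
from .simulate import FishboneConfig, LifespanConfig, generate_fishbone_testing, \
    generate_fishbone_training, generate_lifespan_cohort
from .twin import OnsetBootstrapper, build_twin_pair, detect_pbtl_onset, run_tenfold, \
    summarize_gaps

SPEC = SplineSpec("cubic_bspline", "toep1", 15)

#: structure used for deviation-age recovery: adjusts the arms' sex
#: composition; excludes baseline thalamic volume (a lagged outcome)
RECOVERY_STRUCTURE = CovariateStructure(
    "recovery", (("sex", frozenset({"main", "ms"})),))

#: structure used for patient-level onset estimation: adds the clinical-onset
#: covariate that individualizes the MS curve (zeroed for the twin)
PATIENT_STRUCTURE = CovariateStructure(
    "patient", (("sex", frozenset({"main", "ms"})),
                ("onset_age", frozenset({"main"}))))


def natural_basis_equivalence(seed: int) -> dict:
    """Fit both natural-basis variants on one fish-bone dataset."""
    table = generate_fishbone_training(FishboneConfig(subjects_per_block=20), seed)
    m1 = MixedSplineModel(table, SplineSpec("natural_tpf", "toep1", 15))
    m2 = MixedSplineModel(table, SplineSpec("natural_bspline", "toep1", 15),
                          knots=m1.basis.knots)
    f1, f2 = m1.fit("ML"), m2.fit("ML")
    return {
        "aic_abs_diff": abs(f1.aic - f2.aic),
        "fitted_max_abs_diff": float(np.abs(f1.fitted_values()
                                            - f2.fitted_values()).max()),
    }


def aic_ordering(seed: int, n_reps: int = 50, subjects_per_block: int = 20) -> dict:
    """ML-AIC ordering of basis/penalty structures across fish-bone replicates."""
    cfg = FishboneConfig(subjects_per_block=subjects_per_block)
    rows = []
    for r in range(n_reps):
        table = generate_fishbone_training(cfg, seed + r)
        m = MixedSplineModel(table, SPEC)
        rows.append({
            "cubic_bspline_toep1": m.fit("ML").aic,
            "natural_tpf_toep1": MixedSplineModel(
                table, SplineSpec("natural_tpf", "toep1", 15),
                knots=m.basis.knots).fit("ML").aic,
            "cubic_bspline_pspline": MixedSplineModel(
                table, SplineSpec("cubic_bspline", "pspline", 15),
                knots=m.basis.knots).fit("ML").aic,
        })
    df = pd.DataFrame(rows)
    return {
        "pct_bspline_toep1_beats_natural":
            100.0 * float((df["cubic_bspline_toep1"]
                           <= df["natural_tpf_toep1"]).mean()),
        "pct_toep1_beats_pspline":
            100.0 * float((df["cubic_bspline_toep1"]
                           < df["cubic_bspline_pspline"]).mean()),
        "mean_aic_bspline_toep1": float(df["cubic_bspline_toep1"].mean()),
        "mean_aic_natural_toep1": float(df["natural_tpf_toep1"].mean()),
        "mean_aic_bspline_pspline": float(df["cubic_bspline_pspline"].mean()),
        "n_reps": n_reps,
    }


def gls_oracle(seed: int) -> float:
    """Max |difference| between profiled fixed effects and dense-matrix GLS."""
    cfg = LifespanConfig(n_controls=35, n_ms=15)
    table, _ = generate_lifespan_cohort(cfg, seed)
    model = MixedSplineModel(table, SplineSpec("cubic_bspline", "toep1", 8))
    lam_s, lam_b = 0.7, 2.0
    fit = model.fit("ML", fixed_components=(lam_s, lam_b))
    V = np.eye(model.n_obs) + lam_s * (model.Z @ model.Z.T)
    pos = 0
    for c in model._counts:
        V[pos:pos + c, pos:pos + c] += lam_b
        pos += c
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(model.X.T @ Vi @ model.X, model.X.T @ Vi @ model.y)
    return float(np.abs(fit.fe_params - beta).max())


def onset_recovery(seed: int, n_seeds: int = 20, n_controls: int = 1000,
                   n_ms: int = 300, a0: float = 28.0) -> dict:
    """Deviation-age recovery with a known common deviation age.

    Per cohort: fit the combined model, build each MS patient's twin pair and
    detect the departure age; pooled median absolute error across cohorts.
    """
    errs_all, per_seed = [], []
    for s in range(n_seeds):
        cfg = LifespanConfig(n_controls=n_controls, n_ms=n_ms,
                             common_deviation_age=a0)
        table, _ = generate_lifespan_cohort(cfg, seed + s)
        fit = MixedSplineModel(table, SPEC, RECOVERY_STRUCTURE).fit("ML")
        errs = []
        for _, pat in table.ms().covariates.iterrows():
            det = detect_pbtl_onset(build_twin_pair(fit, pat))
            if np.isfinite(det.age):
                errs.append(det.age - a0)
        errs_all.extend(errs)
        per_seed.append(float(np.median(np.abs(errs))))
    return {
        "median_abs_error_years": float(np.median(np.abs(errs_all))),
        "per_seed_median": per_seed,
        "n_seeds": n_seeds,
    }


def bootstrap_coverage(seed: int, n_cohorts: int = 20, patients_per: int = 5,
                       B: int = 200, a0: float = 28.0) -> dict:
    """Coverage of the 95% bootstrap CI for the deviation age.

    Independent cohorts of 300 controls + 85 MS subjects; 5 patients per
    cohort are held out of training and estimated with the fast-mode
    patient-level bootstrap.  A small full-refit spot check runs on the first
    two cohorts.
    """
    covered, total = 0, 0
    refit_covered, refit_total = 0, 0
    widths = []
    for c in range(n_cohorts):
        cfg = LifespanConfig(n_controls=300, n_ms=80 + patients_per,
                             common_deviation_age=a0)
        table, _ = generate_lifespan_cohort(cfg, seed + 1000 + c)
        ms_ids = np.sort(table.ms().subject_ids())
        test_ids = list(ms_ids[:patients_per])
        train = table.subset_subjects(
            [s for s in table.subject_ids() if s not in set(test_ids)])
        fit = MixedSplineModel(train, SPEC, RECOVERY_STRUCTURE).fit("ML")
        boot = OnsetBootstrapper(fit, B=B, seed=seed + c, mode="fast")
        cov = table.covariates.set_index("subject_id")
        ests = [boot.estimate(cov.loc[sid]) for sid in test_ids]
        for est in ests:
            total += 1
            covered += est.ci_low <= a0 <= est.ci_high
            widths.append(est.ci_high - est.ci_low)
        if c < 2:  # full-refit spot check (10 patients total)
            slow = OnsetBootstrapper(fit, B=60, seed=seed + c, mode="refit")
            for sid in test_ids:
                est = slow.estimate(cov.loc[sid])
                refit_total += 1
                refit_covered += est.ci_low <= a0 <= est.ci_high
    return {
        "coverage_pct": 100.0 * covered / total,
        "n_patients": total,
        "median_ci_width_years": float(np.median(widths)),
        "refit_coverage_pct": 100.0 * refit_covered / max(refit_total, 1),
        "n_refit_patients": refit_total,
    }


def classification_rates(seed: int, n_controls: int = 800, n_ms: int = 250,
                         B: int = 200) -> dict:
    """Earlier/simultaneous labeling under three generating scenarios."""
    out = {}
    scenarios = {
        "strong_early": dict(gap_mean=10.0, gap_sd=1.0),
        "at_onset": dict(gap_mean=0.0, gap_sd=0.0),
        "null_effect": dict(excess_rate=0.0),
    }
    for name, kw in scenarios.items():
        cfg = LifespanConfig(n_controls=n_controls, n_ms=n_ms, **kw)
        table, _ = generate_lifespan_cohort(cfg, seed + 17)
        onsets = run_tenfold(table, SPEC, PATIENT_STRUCTURE, B=B,
                             seed=seed, mode="fast")
        out[f"{name}_earlier_pct"] = 100.0 * float((onsets["label"]
                                                    == "earlier").mean())
        if name == "strong_early":
            out["strong_early_mean_gap_years"] = float(
                (onsets["clinical_onset"] - onsets["pbtl_age"]).mean())
    return out


def augmentation_fidelity(seed: int) -> dict:
    """Noise-free exactness of the rib bones and agreement decay with noise."""
    from .mars import AdaptiveSplineResults, Factor, HingeTerm, predict_adaptive

    # truth inside the model family: augmentation must be exact
    model = AdaptiveSplineResults(
        terms=[HingeTerm(), HingeTerm((Factor("age", "linear"),)),
               HingeTerm((Factor("age", "hinge+", 45.0),))],
        coef=np.array([11.0, -0.015, -0.04]), gcv=0.0, gcv_forward=0.0,
        rss=0.0, n_obs=3, penalty=3.0)
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 80, 80)
    values = predict_adaptive(model, ages, 1e6, "F")
    frame = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(ages))],
        "group": "control", "sex": "F", "age_at_scan": ages,
        "icv_mm3": 1e6, "thalamus_mm3": values * 1e6 / 1000.0,
        "clinical_onset_age": 0.0, "dmt0_years": 0.0,
    })
    from .cohort import build_scan_table
    table = build_scan_table(frame)
    aug = augment_cohort(table, model)
    truth = predict_adaptive(model, aug.scans["age_at_scan"].to_numpy(), 1e6, "F")
    max_err = float(np.abs(aug.scans["norm_thalamus"].to_numpy() - truth).max())

    # ICC between augmented and observed repeats as injected noise grows
    iccs = []
    for noise in (0.0, 0.3, 1.0):
        rng2 = np.random.default_rng(seed + 1)
        base_age = rng2.uniform(25, 78, 150)
        level = predict_adaptive(model, base_age, 1e6, "F") \
            + rng2.normal(0, 0.5, 150)
        train_rows, test_rows = [], []
        for i in range(150):
            train_rows.append((f"t{i}", base_age[i], level[i]))
            for k in (1.0, 2.0):
                drift = (predict_adaptive(model, np.array([base_age[i] + k]), 1e6, "F")
                         - predict_adaptive(model, np.array([base_age[i]]), 1e6, "F"))[0]
                test_rows.append((f"t{i}", base_age[i] + k,
                                  level[i] + drift + rng2.normal(0, noise)))

        def to_table(rows):
            fr = pd.DataFrame(rows, columns=["subject_id", "age_at_scan", "norm"])
            fr["group"], fr["sex"] = "control", "F"
            fr["icv_mm3"] = 1e6
            fr["thalamus_mm3"] = fr.pop("norm") * 1e6 / 1000.0
            fr["clinical_onset_age"] = 0.0
            fr["dmt0_years"] = 0.0
            return build_scan_table(fr)

        aug2 = augment_cohort(to_table(train_rows), model)
        report = validate_augmentation(aug2, to_table(test_rows))
        iccs.append(report.icc.icc)
    return {
        "noise_free_max_abs_error": max_err,
        "icc_noise_free": float(iccs[0]),
        "icc_by_noise": [float(v) for v in iccs],
        "icc_monotone_decreasing": bool(iccs[0] > iccs[1] > iccs[2]),
    }


def structural_counts(seed: int) -> dict:
    """Record counts of the default fish-bone training and testing designs."""
    train = generate_fishbone_training(FishboneConfig(), seed)
    test = generate_fishbone_testing(FishboneConfig(), seed)
    ages_per_subject = test.scan_counts()
    return {
        "training_subjects": int(train.n_subjects),
        "training_records": int(train.n_scans),
        "training_points_per_subject": int(train.scan_counts().iloc[0]),
        "testing_subjects": int(test.n_subjects),
        "testing_ages_per_subject": int(ages_per_subject.iloc[0]),
        "testing_contains_extrapolation_ages": bool(
            {26.0, 27.0, 28.0, 29.0} <= set(test.scans["age_at_scan"])),
    }


def agreement_oracles() -> dict:
    """Hand-table agreement statistics against textbook arithmetic."""
    from .agreement import bland_altman, icc_absolute_agreement

    a = np.array([9.1, 9.7, 8.6, 10.2, 9.0, 9.9])
    b = np.array([9.3, 9.5, 8.9, 10.0, 9.2, 10.3])
    X = np.column_stack([a, b])
    n, k = X.shape
    grand = X.mean()
    msr = k * ((X.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((X.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((X - X.mean(axis=1)[:, None] - X.mean(axis=0)[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    icc_hand = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    pairs = pd.DataFrame({
        "subject": np.repeat(np.arange(n), 2),
        "rater": ["obs", "pred"] * n,
        "value": X.ravel(),
    })
    icc_pkg = icc_absolute_agreement(pairs).icc

    ba = bland_altman([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    ba_hand = (2.0, 1.0, 2.0 - 1.96, 2.0 + 1.96)
    ba_diff = max(abs(ba.mean_diff - ba_hand[0]), abs(ba.sd_diff - ba_hand[1]),
                  abs(ba.loa_low - ba_hand[2]), abs(ba.loa_high - ba_hand[3]))
    return {
        "icc_hand_table_abs_diff": float(abs(icc_pkg - icc_hand)),
        "bland_altman_abs_diff": float(ba_diff),
    }


def realistic_gap_summary(seed: int, n_controls: int = 800, n_ms: int = 250,
                          B: int = 200) -> dict:
    """Headline run under default study conditions (gap ~ N(5, 2) years)."""
    cfg = LifespanConfig(n_controls=n_controls, n_ms=n_ms)
    table, truth = generate_lifespan_cohort(cfg, seed + 29)
    onsets = run_tenfold(table, SPEC, PATIENT_STRUCTURE, B=B, seed=seed,
                         mode="fast")
    summary = summarize_gaps(onsets)
    true_gap = float((truth.subjects.query("group == 'MS'")
                      .merge(table.covariates, on="subject_id")
                      .eval("clinical_onset_age - a0")).mean())
    return {
        "mean_gap_years": summary.mean_gap,
        "median_gap_years": summary.median_gap,
        "earlier_pct": 100.0 * summary.prop_earlier,
        "true_mean_gap_years": true_gap,
        "n_patients": summary.n,
    }
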