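"""Hypothetical-twin trajectories and the onset of progressive brain tissue loss.

For each MS patient the fitted mixed spline model yields two population-level
curves on the age grid 15-75: the MS trajectory (MS indicator on, the
patient's covariates) and the health-digital-twin trajectory (MS indicator
off, clinical-onset age and DMT exposure zeroed, all other covariates
identical).  The age at which the MS curve departs from (crosses below) the
twin curve is the estimated onset of progressive brain tissue loss (PBTL).
Uncertainty comes from a patient-level block bootstrap of the training table:
all scans of a sampled subject move together, the model is refitted per
replicate, and the 2.5/97.5 percentiles of the replicate onsets give the 95%
CI.  A patient is labeled "earlier" onset when the CI's upper limit lies
below their clinical onset age, else "simultaneous".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import BlandAltman, bland_altman
from .cohort import ScanTable
from .mixed import CovariateStructure, MixedSplineModel, MixedSplineResults, _patient_covariates

DEFAULT_GRID = np.arange(15.0, 76.0)


@dataclass
class TrajectoryPair:
    """MS and twin curves with pointwise 95% bands on a common age grid."""

    ages: np.ndarray
    ms: np.ndarray
    ms_lo: np.ndarray
    ms_hi: np.ndarray
    twin: np.ndarray
    twin_lo: np.ndarray
    twin_hi: np.ndarray
    patient: dict


@dataclass
class OnsetDetection:
    age: float
    no_crossing: bool = False
    undetermined: bool = False


@dataclass
class OnsetEstimate:
    """Bootstrap summary of one patient's PBTL onset age."""

    subject_id: str
    pbtl_age: float
    ci_low: float
    ci_high: float
    clinical_onset_age: float
    gap: float  # pbtl_age - clinical_onset_age
    label: str  # "earlier" | "simultaneous"
    n_boot_effective: int
    no_crossing_rate: float
    flagged: bool = False


def twin_profile(patient) -> dict:
    """The twin's covariates: disease covariates zeroed, the rest shared."""
    pc = _patient_covariates(patient)
    twin = dict(pc)
    twin["onset_age"] = 0.0
    twin["dmt0"] = 0.0
    return twin


def build_twin_pair(fit: MixedSplineResults, patient, ages=DEFAULT_GRID,
                    *, level: float = 0.95) -> TrajectoryPair:
    """Patient-specific MS curve and hypothetical normal-aging twin curve."""
    ages = np.asarray(ages, dtype=float)
    pc = _patient_covariates(patient)
    ms, ms_lo, ms_hi = fit.predict(pc, "MS", ages, level=level)
    tw, tw_lo, tw_hi = fit.predict(twin_profile(pc), "control", ages, level=level)
    return TrajectoryPair(ages, ms, ms_lo, ms_hi, tw, tw_lo, tw_hi, pc)


def _detect_from_difference(ages: np.ndarray, d: np.ndarray, delta: float,
                            tol: float) -> OnsetDetection:
    """Departure age from d(a) = twin(a) - ms(a).

    The onset is the changepoint before which the MS curve stays at or above
    the twin (d <= delta) and after which it stays below (d > delta), chosen
    to minimize the number of grid points violating that pattern — for exact
    crossings this is simply the last age with d <= delta, while under noise
    it treats pre-crossing and post-crossing excursions symmetrically.
    Refined by linear interpolation to 0.1-year resolution; if d never
    crosses delta on the grid, the age of minimal |d| is returned with the
    no-crossing flag.
    """
    if np.max(np.abs(d)) < tol:
        return OnsetDetection(np.nan, undetermined=True)
    below = d <= delta
    if not below.any() or below.all():
        return OnsetDetection(float(ages[int(np.argmin(np.abs(d)))]), no_crossing=True)
    if below[-1]:
        return OnsetDetection(float(ages[int(np.argmin(np.abs(d)))]), no_crossing=True)
    # changepoint at i: pattern says d <= delta for j <= i, d > delta after
    above = ~below
    viol_pre = np.cumsum(above)                               # j <= i with d > delta
    viol_post = below[::-1].cumsum()[::-1]                    # j > i with d <= delta
    cost = viol_pre + np.concatenate([viol_post[1:], [0]])
    best = cost.min()
    idx = int(np.flatnonzero(cost == best)[-1])               # ties -> latest
    if idx == len(ages) - 1:
        return OnsetDetection(float(ages[int(np.argmin(np.abs(d)))]), no_crossing=True)
    d0, d1 = d[idx], d[idx + 1]
    t = 0.5 if d1 == d0 else float(np.clip((delta - d0) / (d1 - d0), 0.0, 1.0))
    age = ages[idx] + t * (ages[idx + 1] - ages[idx])
    return OnsetDetection(float(np.round(age, 1)))


def detect_pbtl_onset(pair: TrajectoryPair, *, delta: float = 0.0,
                      tol: float = 1e-6) -> OnsetDetection:
    return _detect_from_difference(pair.ages, pair.twin - pair.ms, delta, tol)


def classify_onset(estimate: OnsetEstimate) -> str:
    """"earlier" iff the CI's upper limit is strictly below clinical onset."""
    if estimate.clinical_onset_age <= 0:
        raise ValueError("classification requires an MS patient with a clinical onset age")
    return "earlier" if estimate.ci_high < estimate.clinical_onset_age else "simultaneous"


class OnsetBootstrapper:
    """Patient-level block bootstrap of a fitted model's trajectory curves.

    Subjects of the training table are resampled with replacement (all scans
    of a subject move as one block) and the model is refitted per replicate.
    ``mode="refit"`` re-estimates the variance components by full ML/REML on
    every replicate; ``mode="fast"`` freezes the variance components at the
    base fit and re-solves only the fixed + penalized coefficients from
    per-subject sufficient statistics (milliseconds per replicate).  The fast
    mode is intended for large simulation harnesses; headline estimates use
    the full refit.

    One bootstrapper serves many patients: the replicate coefficient sets are
    shared, only the patient-specific design rows change.
    """

    def __init__(self, fit: MixedSplineResults, *, B: int = 1000, seed: int = 0,
                 mode: str = "fast"):
        if B < 2:
            raise ValueError("B must be >= 2")
        if mode not in ("fast", "refit"):
            raise ValueError("mode must be 'fast' or 'refit'")
        self.base = fit
        self.model = fit.model
        self.B = int(B)
        self.mode = mode
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
        m = self.model.n_subjects
        p, K = self.model.n_fixed, self.model.n_pen
        coefs = np.full((self.B, p + K), np.nan)
        n_bad = 0
        if mode == "fast":
            lam_s, lam_sub = fit.lam[0], fit.lam[1:]
            A = self.model.per_subject_crossprods(lam_sub)
            ridge = np.zeros(p + K)
            ridge[p:] = 1.0 / lam_s
            for b in range(self.B):
                w = np.bincount(rng.integers(0, m, m), minlength=m).astype(float)
                Cw = np.einsum("m,mcd->cd", w, A)
                H = Cw[: p + K, : p + K] + np.diag(ridge)
                try:
                    coefs[b] = np.linalg.solve(H + 1e-10 * np.eye(p + K), Cw[: p + K, -1])
                except np.linalg.LinAlgError:
                    n_bad += 1
        else:
            table = self.model.table
            ids = self.model.subject_ids
            for b in range(self.B):
                take = ids[rng.integers(0, m, m)]
                rep = _resample_table(table, take)
                try:
                    r = MixedSplineModel(
                        rep, self.model.spec, self.model.structure,
                        basis=self.model.basis, standardize=self.model.standardize,
                        subject_slope=self.model.subject_slope,
                        ms_poly=self.model.ms_poly,
                        interaction_proj=self.model._interaction_proj,
                    ).fit(fit.method)
                except Exception:
                    n_bad += 1
                    continue
                if not r.converged:
                    n_bad += 1
                    continue
                coefs[b] = np.concatenate([r.fe_params, r.blups])
        self.coefs = coefs
        self.n_failed = n_bad

    def estimate(self, patient, *, ages=DEFAULT_GRID, delta: float = 0.0,
                 tol: float = 1e-6) -> OnsetEstimate:
        pc = _patient_covariates(patient)
        onset = float(pc.get("onset_age", 0.0))
        ages = np.asarray(ages, dtype=float)
        Xm, Zm = self.model.design_rows(pc, "MS", ages)
        Xt, Zt = self.model.design_rows(twin_profile(pc), "control", ages)
        Rm = np.column_stack([Xm, Zm])
        Rt = np.column_stack([Xt, Zt])
        good = ~np.isnan(self.coefs).any(axis=1)
        diffs = (self.coefs[good] @ Rt.T) - (self.coefs[good] @ Rm.T)
        vals, n_nc = [], 0
        for d in diffs:
            det = _detect_from_difference(ages, d, delta, tol)
            if det.undetermined:
                continue
            n_nc += det.no_crossing
            vals.append(det.age)
        vals = np.asarray(vals, dtype=float)
        n_eff = len(vals)
        if n_eff == 0:
            est = OnsetEstimate(str(pc.get("subject_id", "?")), np.nan, np.nan, np.nan,
                                onset, np.nan, "simultaneous", 0, 0.0, flagged=True)
            return est
        point = float(vals.mean())
        lo, hi = np.percentile(vals, [2.5, 97.5])
        est = OnsetEstimate(
            subject_id=str(pc.get("subject_id", "?")),
            pbtl_age=point, ci_low=float(lo), ci_high=float(hi),
            clinical_onset_age=onset, gap=point - onset,
            label="", n_boot_effective=n_eff,
            no_crossing_rate=n_nc / n_eff,
            flagged=n_eff < self.B / 2,
        )
        est.label = classify_onset(est) if onset > 0 else "simultaneous"
        return est


def _resample_table(table: ScanTable, take) -> ScanTable:
    """Assemble a bootstrap table; duplicated subjects get fresh unique ids."""
    groups = dict(tuple(table.scans.groupby("subject_id", sort=False)))
    cov = table.covariates.set_index("subject_id", drop=False)
    s_pieces, c_pieces = [], []
    for k, sid in enumerate(take):
        g = groups[sid].copy()
        new_id = f"B{k:05d}"
        g["subject_id"] = new_id
        s_pieces.append(g)
        c = cov.loc[[sid]].copy()
        c["subject_id"] = new_id
        c_pieces.append(c)
    scans = pd.concat(s_pieces, ignore_index=True)
    scans = scans.sort_values(["subject_id", "age_at_scan"], kind="mergesort").reset_index(drop=True)
    covs = pd.concat(c_pieces, ignore_index=True)
    return ScanTable(scans, covs)


def bootstrap_onset_ci(table: ScanTable, spec, structure: CovariateStructure, patient,
                       *, B: int = 1000, seed: int = 0, mode: str = "refit",
                       method: str = "ML", ages=DEFAULT_GRID) -> OnsetEstimate:
    """Fit on ``table`` (which must exclude the patient) and bootstrap their onset."""
    pc = _patient_covariates(patient)
    sid = str(pc.get("subject_id", ""))
    if sid and sid in set(table.subject_ids()):
        raise ValueError("patient must not appear in the training table")
    fit = MixedSplineModel(table, spec, structure).fit(method)
    boot = OnsetBootstrapper(fit, B=B, seed=seed, mode=mode)
    return boot.estimate(pc, ages=ages)


def run_tenfold(table: ScanTable, spec, structure: CovariateStructure, *,
                B: int = 200, seed: int = 0, n_folds: int = 10, mode: str = "fast",
                method: str = "ML", ages=DEFAULT_GRID) -> pd.DataFrame:
    """Tenfold cross-validated onset estimation for every MS subject.

    MS subjects are partitioned into ``n_folds`` mutually exclusive folds by a
    seeded permutation of the sorted ids; each fold's patients are estimated
    from a model fitted on the remaining MS subjects plus all controls.
    """
    ms_ids = np.sort(table.ms().subject_ids())
    if len(ms_ids) < 2 * n_folds:
        raise ValueError("too few MS subjects for the requested folds")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    perm = rng.permutation(len(ms_ids))
    folds = [sorted(ms_ids[perm[i::n_folds]]) for i in range(n_folds)]
    cov = table.covariates.set_index("subject_id", drop=False)
    rows = []
    for f, fold_ids in enumerate(folds):
        if not fold_ids:
            raise ValueError("empty fold")
        keep = [s for s in table.subject_ids() if s not in set(fold_ids)]
        train = table.subset_subjects(keep)
        assert not (set(train.subject_ids()) & set(fold_ids))
        fit = MixedSplineModel(train, spec, structure).fit(method)
        boot = OnsetBootstrapper(fit, B=B, seed=seed + 7919 * (f + 1), mode=mode)
        for sid in fold_ids:
            est = boot.estimate(cov.loc[sid], ages=ages)
            rows.append(
                dict(subject_id=sid, fold=f, pbtl_age=est.pbtl_age, ci_low=est.ci_low,
                     ci_high=est.ci_high, clinical_onset=est.clinical_onset_age,
                     gap=est.gap, label=est.label, n_boot_effective=est.n_boot_effective,
                     no_crossing_rate=est.no_crossing_rate, flagged=est.flagged)
            )
    return pd.DataFrame(rows)


@dataclass
class GapSummary:
    """Distribution of clinical-onset minus PBTL-onset gaps across patients."""

    n: int
    mean_gap: float
    sd_gap: float
    median_gap: float
    iqr: tuple
    prop_earlier: float
    prop_simultaneous: float
    bland_altman_all: BlandAltman
    bland_altman_by_label: dict = field(default_factory=dict)
    mean_no_crossing_rate: float = 0.0

    def summary(self) -> str:
        lo, hi = self.iqr
        return (
            f"n={self.n}; clinical - PBTL gap mean {self.mean_gap:.1f} +- {self.sd_gap:.1f} y, "
            f"median {self.median_gap:.1f} (IQR {lo:.1f}-{hi:.1f}); "
            f"earlier {100 * self.prop_earlier:.1f}% / simultaneous "
            f"{100 * self.prop_simultaneous:.1f}%"
        )


def summarize_gaps(onsets: pd.DataFrame) -> GapSummary:
    """Gap statistics and Bland-Altman inputs from an onset table."""
    if len(onsets) < 2:
        raise ValueError("need >= 2 onset estimates")
    df = onsets.dropna(subset=["pbtl_age"])
    gaps = (df["clinical_onset"] - df["pbtl_age"]).to_numpy(dtype=float)
    q1, q3 = np.percentile(gaps, [25, 75])
    ba_all = bland_altman(df["pbtl_age"].to_numpy(), df["clinical_onset"].to_numpy())
    by_label = {}
    for lab, grp in df.groupby("label"):
        if len(grp) >= 2:
            by_label[lab] = bland_altman(grp["pbtl_age"].to_numpy(),
                                         grp["clinical_onset"].to_numpy())
    sd = float(gaps.std(ddof=1)) if len(gaps) > 1 else 0.0
    return GapSummary(
        n=len(df),
        mean_gap=float(gaps.mean()),
        sd_gap=sd,
        median_gap=float(np.median(gaps)),
        iqr=(float(q1), float(q3)),
        prop_earlier=float((df["label"] == "earlier").mean()),
        prop_simultaneous=float((df["label"] == "simultaneous").mean()),
        bland_altman_all=ba_all,
        bland_altman_by_label=by_label,
        mean_no_crossing_rate=float(df["no_crossing_rate"].mean()),
    )
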