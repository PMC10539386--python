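"""Enumerate and score candidate spline structures and covariate structures.

Twelve spline structures (4 bases x 3 penalties) and a covariate catalog grown
by staged rules — (a) main effects, (b) two-way x MS, (c) three-way
covariate x MS x age-spline one at a time, (d)-(f) pairs/triples/quadruples of
three-ways, (g) backward reductions that keep a bundle's two-way components
while dropping its three-way — are ranked on four criteria: training AIC/BIC,
held-out repeated-measures correlation and ICC, trajectory-shape concordance
with the cross-sectional normal-aging curve, and the width of the predicted
confidence band along the age grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import icc_absolute_agreement, rmcorr
from .bases import BASES, PENALTIES, SplineSpec
from .cohort import ScanTable
from .mixed import (
    COVARIATES,
    NO_THREE_WAY,
    CovariateStructure,
    MixedSplineModel,
    mandatory_structure,
)

THREE_WAY_ELIGIBLE = tuple(c for c in COVARIATES if c not in NO_THREE_WAY)


def enumerate_spline_specs(n_knots: int = 15) -> list[SplineSpec]:
    """The 12 candidate basis/penalty structures in stable basis-major order."""
    return [SplineSpec(b, p, n_knots) for b in BASES for p in PENALTIES]


def _structure(name: str, comps: dict) -> CovariateStructure:
    terms = tuple((c, frozenset(comps[c])) for c in COVARIATES if c in comps)
    return CovariateStructure(name, terms)


def final_paper_structure() -> CovariateStructure:
    """The published final covariate structure.

    All six covariate main effects plus the sex x MS and sex x age-spline
    two-way interactions (a stage-(g) reduction of the sex three-way bundle).
    """
    comps = {c: {"main"} for c in COVARIATES}
    comps["sex"] = {"main", "ms", "spline"}
    return _structure("final", comps)


def enumerate_covariate_catalog() -> list[CovariateStructure]:
    """Generate the covariate-structure catalog from the staged rules.

    Deterministic; the mandatory block is implicit in every structure.  The
    rules produce more than the historically quoted 52 structures (the
    original list was never published); the catalog always contains the
    published final structure.
    """
    out = [mandatory_structure()]
    all_main = {c: {"main"} for c in COVARIATES}

    # (a) main effects: one by one, then all together
    for i, c in enumerate(COVARIATES, 1):
        out.append(_structure(f"a{i}", {c: {"main"}}))
    out.append(_structure("a7", all_main))

    # (b) two-way x MS: one by one on top of all mains, then combined
    for i, c in enumerate(COVARIATES, 1):
        comps = {k: set(v) for k, v in all_main.items()}
        comps[c] = {"main", "ms"}
        out.append(_structure(f"b{i}", comps))
    out.append(_structure("b7", {c: {"main", "ms"} for c in COVARIATES}))

    # (c)-(f): three-way bundles for eligible covariates
    bundle = {"main", "ms", "spline", "ms_spline"}
    stage_cf = []
    for size, stage in ((1, "c"), (2, "d"), (3, "e"), (4, "f")):
        for i, covs in enumerate(itertools.combinations(THREE_WAY_ELIGIBLE, size), 1):
            comps = {k: set(v) for k, v in all_main.items()}
            for c in covs:
                comps[c] = set(bundle)
            s = _structure(f"{stage}{i}", comps)
            stage_cf.append((s, covs))
            out.append(s)

    # (g) backward reductions: demote one three-way bundle to its two-ways
    gi = 1
    for s, covs in stage_cf:
        for c in covs:
            comps = {cov: set(cmp) for cov, cmp in s.terms}
            comps[c] = {"main", "ms", "spline"}
            out.append(_structure(f"g{gi}", comps))
            gi += 1

    # dedupe on term content, keeping first occurrence; force-include final
    seen, cat = set(), []
    for s in out + [final_paper_structure()]:
        key = s.terms
        if key not in seen:
            seen.add(key)
            cat.append(s)
    return cat


@dataclass
class ModelChoice:
    spec: SplineSpec
    structure_name: str
    audit: dict = field(default_factory=dict)


def holdout_split(table: ScanTable, fraction: float = 0.1, seed: int = 0):
    """Subject-level split reserving ``fraction`` of MS subjects for testing."""
    ms_ids = np.sort(table.ms().subject_ids())
    if len(ms_ids) == 0:
        raise ValueError("no MS subjects to hold out")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    perm = rng.permutation(len(ms_ids))
    n_hold = max(1, int(round(fraction * len(ms_ids))))
    hold = set(ms_ids[perm[:n_hold]])
    train = table.subset_subjects([s for s in table.subject_ids() if s not in hold])
    test = table.subset_subjects(hold)
    assert not (set(train.subject_ids()) & set(test.subject_ids()))
    return train, test


def _holdout_scores(result, test: ScanTable):
    pred = result.predict_scans(test)
    obs = test.scans["norm_thalamus"].to_numpy()
    sid = test.scans["subject_id"].to_numpy()
    df = pd.DataFrame({"subject": sid, "x": pred, "y": obs})
    try:
        r = rmcorr(df).r
    except ValueError:
        r = np.nan
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(len(df)), 2),
            "rater": ["pred", "obs"] * len(df),
            "value": np.column_stack([pred, obs]).ravel(),
        }
    )
    try:
        icc = icc_absolute_agreement(long).icc
    except ValueError:
        icc = np.nan
    return r, icc


def _reference_patient(table: ScanTable) -> dict:
    cov = table.covariates
    ctrl = cov[cov["group"] == "control"]
    base = ctrl if len(ctrl) else cov
    return {
        "sex": float((base["sex"] == "F").mean().round()),
        "thalamus0": float(base["thalamus0"].mean()),
        "icv0": float(base["icv0"].mean()),
        "onset_age": 0.0,
        "dmt0": 0.0,
        "entry_age": float(base["age_at_entry"].mean()),
    }


def evaluate_candidates(table: ScanTable, specs, structures, *,
                        holdout_fraction: float = 0.1, seed: int = 0,
                        method: str = "ML", reference_curve=None,
                        grid=None, fold_id: int = 0) -> pd.DataFrame:
    """Fit every spec x structure candidate and score the four criteria.

    Returns one row per candidate with training AIC/BIC, held-out rmcorr and
    ICC on the reserved MS subjects, mean 95% band half-width on the age grid
    and (when ``reference_curve`` is given) the Pearson shape concordance of
    the fitted control lifespan curve with the cross-sectional reference.
    """
    grid = np.arange(15.0, 76.0) if grid is None else np.asarray(grid, dtype=float)
    train, test = holdout_split(table, holdout_fraction, seed)
    ref = None if reference_curve is None else np.asarray(reference_curve(grid), dtype=float)
    patient = _reference_patient(train)
    rows = []
    for spec in specs:
        for structure in structures:
            rec = dict(fold=fold_id, spec=spec.id, structure=structure.name)
            try:
                fit = MixedSplineModel(train, spec, structure).fit(method)
            except Exception as exc:  # rank deficiency etc. -> flagged, excluded
                rec.update(converged=False, error=str(exc)[:80])
                rows.append(rec)
                continue
            rec.update(converged=fit.converged, aic=fit.aic, bic=fit.bic, llf=fit.llf)
            r, icc = _holdout_scores(fit, test)
            rec.update(rmcorr=r, icc=icc)
            curve, lo, hi = fit.predict(patient, "control", grid)
            rec["band_halfwidth"] = float(np.mean((hi - lo) / 2.0))
            if ref is not None:
                rec["shape_concordance"] = float(np.corrcoef(curve, ref)[0, 1])
            rows.append(rec)
    return pd.DataFrame(rows)


def select_final(comparison: pd.DataFrame, *, shape_min: float = 0.9,
                 band_factor: float = 1.5, specs=None, structures=None) -> ModelChoice:
    """Apply the shape/band screens, then rank by AIC with tie-breaking.

    Candidates failing shape concordance >= ``shape_min`` or whose mean band
    half-width exceeds ``band_factor`` x the narrowest candidate are screened
    out; survivors are ranked by AIC, then BIC, then held-out rmcorr, then
    lexicographic candidate id.
    """
    if comparison.empty:
        raise ValueError("empty comparison table")
    df = comparison[comparison.get("converged", True) == True].copy()  # noqa: E712
    if df.empty:
        raise ValueError("no converged candidates")
    audit = {"n_candidates": len(comparison), "n_converged": len(df)}
    if "shape_concordance" in df.columns and df["shape_concordance"].notna().any():
        kept = df[df["shape_concordance"] >= shape_min]
        audit["n_pass_shape"] = len(kept)
        if not kept.empty:
            df = kept
    if "band_halfwidth" in df.columns and df["band_halfwidth"].notna().any():
        cap = band_factor * df["band_halfwidth"].min()
        kept = df[df["band_halfwidth"] <= cap]
        audit["band_cap"] = float(cap)
        audit["n_pass_band"] = len(kept)
        if not kept.empty:
            df = kept
    if df.empty:
        raise ValueError("all candidates screened out; relax shape/band thresholds")
    df = df.copy()
    df["_rm"] = -df.get("rmcorr", pd.Series(np.nan, index=df.index)).fillna(-np.inf)
    df = df.sort_values(["aic", "bic", "_rm", "spec", "structure"], kind="mergesort")
    best = df.iloc[0]
    audit["ranking_head"] = df[["spec", "structure", "aic"]].head(5).to_dict("records")
    basis, penalty = best["spec"].split("+")
    spec = SplineSpec(basis, penalty)
    if specs is not None:
        spec = next(s for s in specs if s.id == best["spec"])
    return ModelChoice(spec=spec, structure_name=str(best["structure"]), audit=audit)
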