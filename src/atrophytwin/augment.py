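"""Grow pseudo-longitudinal "rib bones" around each control scan.

Each observed control scan at age ``a`` with value ``y_obs`` spawns records at
``a + k`` for yearly offsets k in {-2,...,+2} with value
``y_obs + [f(a+k) - f(a)]`` evaluated from the cross-sectional model ``f`` with
the subject's ICV and sex held constant.  The observation anchors the level
(preserving between-subject variance); the model contributes only the local
age slope.  Augmented records carry ``is_augmented=True``; no noise is added
by default (optional residual injection for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import IccResult, RmCorrResult, icc_absolute_agreement, rmcorr
from .cohort import ScanTable
from .mars import AdaptiveSplineResults, predict_adaptive

DEFAULT_OFFSETS = (-2.0, -1.0, 0.0, 1.0, 2.0)


def augment_cohort(table: ScanTable, model: AdaptiveSplineResults,
                   offsets=DEFAULT_OFFSETS, *, noise_sd: float = 0.0,
                   seed: int | None = None) -> ScanTable:
    """Emit the rib-bone records for every observed control scan.

    The offset-0 record is the observation itself.  When one subject has
    several true scans, overlapping augmented ages are resolved by keeping the
    record derived from the nearest observed scan.
    """
    scans = table.scans
    if (scans["group"] != "control").any():
        raise ValueError("augmentation applies to the normal-aging arm only")
    if scans["is_augmented"].any():
        raise ValueError("input table already contains augmented records")
    offsets = np.asarray(sorted(offsets), dtype=float)
    if 0.0 not in offsets:
        raise ValueError("offsets must include 0 (the observed scan)")

    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    age = scans["age_at_scan"].to_numpy()
    icv = scans["icv_mm3"].to_numpy()
    sex = (scans["sex"] == "F").astype(float).to_numpy()
    y_obs = scans["norm_thalamus"].to_numpy()
    f_at = predict_adaptive(model, age, icv, sex)

    pieces = []
    for k in offsets:
        value = y_obs + (predict_adaptive(model, age + k, icv, sex) - f_at)
        if rng is not None and k != 0.0:
            value = value + rng.normal(0.0, noise_sd, len(value))
        out = scans.copy()
        out["age_at_scan"] = age + k
        out["norm_thalamus"] = value
        out["thalamus_mm3"] = value * icv / 1000.0
        out["is_augmented"] = k != 0.0
        out["offset_abs"] = abs(k)
        pieces.append(out)
    aug = pd.concat(pieces, ignore_index=True)
    # collision rule: keep the record from the nearest observed scan
    aug = aug.sort_values(["subject_id", "age_at_scan", "offset_abs"], kind="mergesort")
    aug = aug.drop_duplicates(subset=["subject_id", "age_at_scan"], keep="first")
    aug = aug.drop(columns="offset_abs").reset_index(drop=True)
    aug = aug.sort_values(["subject_id", "age_at_scan"], kind="mergesort").reset_index(drop=True)
    return ScanTable(aug, table.covariates.copy())


@dataclass
class AgreementReport:
    """Agreement between model-augmented and held-out observed repeats."""

    icc: IccResult
    rmcorr: RmCorrResult
    n_pairs: int

    def summary(self) -> str:
        i, r = self.icc, self.rmcorr
        return (
            f"{self.n_pairs} matched pairs\n"
            f"ICC(A,1) {i.icc:.3f} 95% CI ({i.ci_low:.3f}, {i.ci_high:.3f})\n"
            f"rmcorr   {r.r:.3f} 95% CI ({r.ci_low:.3f}, {r.ci_high:.3f}), p={r.p:.2g}"
        )


def validate_augmentation(augmented: ScanTable, observed_repeats: ScanTable,
                          *, max_age_gap: float = 0.5) -> AgreementReport:
    """Pair augmented values with held-out observed repeats and score agreement.

    For every observed scan of a held-out subject, the augmented record of the
    same subject with the nearest age (within ``max_age_gap`` years) provides
    the model-predicted value.  Agreement is summarized with ICC(A,1) and the
    repeated-measures correlation.
    """
    obs = observed_repeats.scans
    aug = augmented.scans
    pairs = []
    by_subject = dict(tuple(aug.groupby("subject_id", sort=False)))
    for sid, grp in obs.groupby("subject_id", sort=True):
        cand = by_subject.get(sid)
        if cand is None:
            continue
        ca = cand["age_at_scan"].to_numpy()
        cv = cand["norm_thalamus"].to_numpy()
        for a, v in zip(grp["age_at_scan"].to_numpy(), grp["norm_thalamus"].to_numpy()):
            j = int(np.argmin(np.abs(ca - a)))
            if abs(ca[j] - a) <= max_age_gap:
                pairs.append((sid, a, cv[j], v))
    if not pairs:
        raise ValueError("no matched subject/age pairs between tables")
    df = pd.DataFrame(pairs, columns=["subject", "age", "augmented", "observed"])

    # ICC treats each matched scan as a target rated twice (augmented/observed)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(len(df)), 2),
            "rater": ["augmented", "observed"] * len(df),
            "value": np.column_stack([df["augmented"], df["observed"]]).ravel(),
        }
    )
    icc = icc_absolute_agreement(long)
    rm = rmcorr(df, subject="subject", x="augmented", y="observed")
    return AgreementReport(icc=icc, rmcorr=rm, n_pairs=len(df))
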