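"""Long-format MRI scan tables: data model, CSV I/O, normalization, filtering.

A :class:`ScanTable` holds one row per scan (subject, group, age, volumes) plus a
per-subject covariate frame (sex, baseline volumes, clinical onset age, DMT
exposure).  The modeled response is the normalized thalamic volume,
``thalamus / ICV * 1000`` (dimensionless, around 9-10 in adults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("control", "MS")
SEXES = ("F", "M")

#: required columns of the external CSV format
REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "sex",
    "age_at_scan",
    "icv_mm3",
    "thalamus_mm3",
    "clinical_onset_age",
    "dmt0_years",
)
OPTIONAL_COLUMNS = ("norm_thalamus", "source", "is_augmented")

#: relative tolerance used to cross-check a supplied norm_thalamus column
NORM_RTOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """One or more rows violate the scan-table invariants.

    The ``report`` attribute lists ``(row_index, message)`` pairs.
    """

    def __init__(self, report):
        self.report = list(report)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.report[:20])
        more = "" if len(self.report) <= 20 else f" (+{len(self.report) - 20} more)"
        super().__init__(f"{len(self.report)} invalid rows: {lines}{more}")


def normalize_thalamus(thalamus, icv):
    """Normalized thalamic volume: ``thalamus / icv * 1000``.

    Both arguments are in mm^3; the result is dimensionless and scale-invariant
    (multiplying both volumes by a constant leaves it unchanged).

    Raises
    ------
    ValueError
        If any ``icv`` is not strictly positive.
    """
    thalamus = np.asarray(thalamus, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if np.any(icv <= 0):
        raise ValueError("icv must be > 0")
    out = thalamus / icv * 1000.0
    return float(out) if out.ndim == 0 else out


@dataclass
class ScanTable:
    """Validated long-format scan table joined to per-subject covariates.

    Attributes
    ----------
    scans : pandas.DataFrame
        One row per scan with columns ``subject_id, group, sex, age_at_scan,
        icv_mm3, thalamus_mm3, norm_thalamus, clinical_onset_age, dmt0_years,
        source, is_augmented``, sorted by (subject_id, age_at_scan).
    covariates : pandas.DataFrame
        One row per subject: ``subject_id, group, sex, thalamus0, icv0,
        age_at_entry, clinical_onset_age, dmt0``.  Baselines are taken from
        each subject's earliest non-augmented scan.
    """

    scans: pd.DataFrame
    covariates: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.covariates is None:
            self.covariates = derive_covariates(self.scans)

    # -- basic properties -------------------------------------------------
    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def subject_ids(self):
        return self.covariates["subject_id"].to_numpy()

    def scan_counts(self) -> pd.Series:
        return self.scans.groupby("subject_id", sort=True).size()

    def subset_subjects(self, ids) -> "ScanTable":
        ids = set(ids)
        scans = self.scans[self.scans["subject_id"].isin(ids)].reset_index(drop=True)
        cov = self.covariates[self.covariates["subject_id"].isin(ids)].reset_index(drop=True)
        return ScanTable(scans, cov)

    def controls(self) -> "ScanTable":
        return self.subset_subjects(
            self.covariates.loc[self.covariates["group"] == "control", "subject_id"]
        )

    def ms(self) -> "ScanTable":
        return self.subset_subjects(
            self.covariates.loc[self.covariates["group"] == "MS", "subject_id"]
        )

    def concat(self, other: "ScanTable") -> "ScanTable":
        scans = pd.concat([self.scans, other.scans], ignore_index=True)
        scans = scans.sort_values(["subject_id", "age_at_scan"], kind="mergesort").reset_index(
            drop=True
        )
        cov = pd.concat([self.covariates, other.covariates], ignore_index=True)
        cov = cov.sort_values("subject_id", kind="mergesort").reset_index(drop=True)
        return ScanTable(scans, cov)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
        self.scans.to_csv(path, index=False, columns=cols, float_format="%.17g")

    def __len__(self):
        return len(self.scans)


def _coerce_scans(frame: pd.DataFrame, schema: dict | None = None) -> pd.DataFrame:
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = frame.copy()
    for col in ("age_at_scan", "icv_mm3", "thalamus_mm3", "clinical_onset_age", "dmt0_years"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "source" not in df.columns:
        df["source"] = "unknown"
    if "is_augmented" not in df.columns:
        df["is_augmented"] = False
    df["is_augmented"] = df["is_augmented"].astype(bool)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def validate_scans(df: pd.DataFrame) -> pd.DataFrame:
    """Validate row invariants; returns the frame with norm_thalamus filled in.

    Collects every violation into a single :class:`ValidationError` so a data
    file can be repaired in one pass.
    """
    report = []
    for col in ("age_at_scan", "icv_mm3", "thalamus_mm3"):
        for i in df.index[df[col].isna()]:
            report.append((i, f"non-numeric {col}"))
    ok = ~df[["age_at_scan", "icv_mm3", "thalamus_mm3"]].isna().any(axis=1)

    bad_group = ~df["group"].isin(GROUPS)
    for i in df.index[bad_group]:
        report.append((i, f"unknown group {df.at[i, 'group']!r}"))
    bad_sex = ~df["sex"].isin(SEXES)
    for i in df.index[bad_sex]:
        report.append((i, f"unknown sex {df.at[i, 'sex']!r}"))

    nonpos = ok & ((df["icv_mm3"] <= 0) | (df["thalamus_mm3"] <= 0))
    for i in df.index[nonpos]:
        report.append((i, "non-positive volume"))
    big = ok & ~nonpos & (df["thalamus_mm3"] >= df["icv_mm3"])
    for i in df.index[big]:
        report.append((i, "thalamus >= icv"))

    usable = ok & ~nonpos & ~big
    computed = np.full(len(df), np.nan)
    computed[usable.to_numpy()] = (
        df.loc[usable, "thalamus_mm3"] / df.loc[usable, "icv_mm3"] * 1000.0
    )
    if "norm_thalamus" in df.columns and df["norm_thalamus"].notna().any():
        supplied = pd.to_numeric(df["norm_thalamus"], errors="coerce")
        have = usable & supplied.notna()
        rel = np.abs(supplied[have] - computed[have.to_numpy()]) / np.maximum(
            np.abs(computed[have.to_numpy()]), 1e-300
        )
        for i in have.index[have][rel > NORM_RTOL]:
            report.append((i, "norm_thalamus inconsistent with thalamus/icv*1000"))
    df = df.copy()
    df["norm_thalamus"] = computed

    # duplicate (subject, age) pairs: the trajectory models index scans by age
    dup = df.duplicated(subset=["subject_id", "age_at_scan"], keep=False) & ~df.duplicated(
        subset=["subject_id", "age_at_scan"], keep="first"
    )
    for i in df.index[dup]:
        report.append((i, "duplicate age for subject"))

    # control subjects carry no disease covariates
    ctrl = df["group"] == "control"
    for i in df.index[ctrl & ((df["clinical_onset_age"] != 0) | (df["dmt0_years"] != 0))]:
        report.append((i, "control with nonzero clinical_onset_age or dmt0"))

    if report:
        raise ValidationError(sorted(report))
    return df


def derive_covariates(scans: pd.DataFrame) -> pd.DataFrame:
    """Per-subject covariates from each subject's earliest non-augmented scan."""
    base = scans[~scans["is_augmented"]]
    if base.empty:
        base = scans
    first = (
        base.sort_values(["subject_id", "age_at_scan"], kind="mergesort")
        .groupby("subject_id", sort=True, as_index=False)
        .first()
    )
    cov = pd.DataFrame(
        {
            "subject_id": first["subject_id"],
            "group": first["group"],
            "sex": first["sex"],
            "thalamus0": first["norm_thalamus"],
            "icv0": first["icv_mm3"],
            "age_at_entry": first["age_at_scan"],
            "clinical_onset_age": first["clinical_onset_age"],
            "dmt0": first["dmt0_years"],
        }
    )
    ms = cov["group"] == "MS"
    bad = ms & (cov["clinical_onset_age"] > cov["age_at_entry"])
    if bad.any():
        ids = cov.loc[bad, "subject_id"].tolist()
        raise ValidationError([(i, "clinical onset after study entry") for i in ids])
    return cov.reset_index(drop=True)


def build_scan_table(frame: pd.DataFrame, schema: dict | None = None) -> ScanTable:
    """Validate a raw frame and assemble a :class:`ScanTable`."""
    df = _coerce_scans(frame, schema)
    df = validate_scans(df)
    df = df.sort_values(["subject_id", "age_at_scan"], kind="mergesort").reset_index(drop=True)
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    return ScanTable(df[cols])


def load_scan_table(path, schema: dict | None = None) -> ScanTable:
    """Read a comma-delimited UTF-8 scan CSV and validate it.

    ``schema`` optionally maps canonical column names to the file's column
    names (``{"subject_id": "SID", ...}``).  ``norm_thalamus`` is computed when
    absent and cross-checked (to 1e-6 relative) when present.
    """
    frame = pd.read_csv(path)
    return build_scan_table(frame, schema)


def apply_age_filter(table: ScanTable, min_age: float = 16.0, max_age: float = 90.0) -> ScanTable:
    """Drop scans outside [min_age, max_age]; boundary ages are retained.

    The bounds follow the exclusion of scans younger than 16 (brain growth
    confound) or older than 90.  Subjects left with no scans are removed from
    the covariate frame.  Augmented rib-bone records are exempt: their ages may
    exceed the window by the augmentation offset by construction.  Idempotent.
    """
    if min_age >= max_age:
        raise ValueError("min_age must be < max_age")
    s = table.scans
    keep = ((s["age_at_scan"] >= min_age) & (s["age_at_scan"] <= max_age)) | s["is_augmented"]
    scans = s[keep].reset_index(drop=True)
    remaining = set(scans["subject_id"])
    cov = table.covariates[table.covariates["subject_id"].isin(remaining)].reset_index(drop=True)
    return ScanTable(scans, cov)
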