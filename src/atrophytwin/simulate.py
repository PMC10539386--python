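"""Synthetic cohorts with known ground truth.

Two generators:

* :func:`generate_lifespan_cohort` emulates the statistical structure of the
  real cohorts — a large, mostly cross-sectional normal-aging arm spanning ages
  16-90 (a minority with 2-4 repeated scans over ~2.5 years) and an MS arm with
  ~4 annual scans per subject clustered in mid-life — with a known per-subject
  deviation age ``a0`` at which excess atrophy begins.

* :func:`generate_fishbone_training` / :func:`generate_fishbone_testing`
  implement the block linear mixed model used to study the "fish bone" data
  structure: 10 five-year age blocks from 30 to 80, block-specific weights
  (W_k, V_k) on the fixed intercept and slope bending the backbone into a
  spline shape, subject random intercept/slope, and iid Gaussian noise::

      Y_kij = W_k*b00 + V_k*b10*Year + b01*MS + b11*MS*Year
              + u0_j + u1_j*Year + eps_kij,   eps ~ N(0, sigma^2)

All randomness flows through a single seeded generator; per-operation streams
are derived with fixed offsets so each operation is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ScanTable, build_scan_table

# emulates the cohort mix of the normal-aging sources: a dense young component,
# young adults, older adults, a mid-life clinical-site component and an elderly
# component (counts 178/865/676/87/247 out of 2053)
_CONTROL_AGE_MIXTURE = (
    # (count, age mean, age sd, repeat weight): repeat scans concentrate in the
    # elderly longitudinal component and the mid-life clinical-site component
    (178, 19.0, 2.0, 0.0),
    (865, 29.0, 4.0, 0.05),
    (676, 58.0, 14.0, 0.1),
    (87, 40.0, 11.0, 3.0),
    (247, 75.0, 7.0, 3.5),
)


@dataclass
class LifespanConfig:
    """Study conditions for the lifespan cohort generator.

    Defaults reproduce the real cohorts' published structure: 2053 controls /
    519 MS; 4 +- 1.5 annual MS scans; ~11% of controls with 2-4 repeats over
    ~2.5 years; clinical onset 33.5 +- 9.1 y with entry ~9 y later; DMT
    exposure ~2.5 y; normalized thalamic volume ~9.7 +- 1 in controls and
    9.3 +- 1 in MS at entry.  The deviation age ``a0`` defaults to clinical
    onset minus a Normal(5, 2) gap, and excess atrophy accrues linearly at
    ``excess_rate`` per year after ``a0``.
    """

    n_controls: int = 2053
    n_ms: int = 519
    control_repeat_fraction: float = 228 / 2053
    repeat_scans_mean: float = 2.9
    repeat_scans_sd: float = 1.0
    repeat_span_years: float = 2.5
    repeat_span_sd: float = 1.4
    ms_scans_mean: float = 4.0
    ms_scans_sd: float = 1.5
    subject_sd: float = 0.65
    residual_sd: float = 0.15
    excess_rate: float = 0.03
    excess_shape: str = "linear"  # or "quadratic" (smooth-onset ramp)
    gap_mean: float = 5.0
    gap_sd: float = 2.0
    common_deviation_age: float | None = None
    onset_mean: float = 33.5
    onset_sd: float = 9.1
    entry_gap_mean: float = 9.2
    entry_gap_sd: float = 5.0
    ms_female_fraction: float = 0.70
    control_female_fraction: float = 0.56
    icv_female_mean: float = 1.40e6
    icv_male_mean: float = 1.55e6
    icv_sd: float = 1.2e5
    sex_effect: float = 0.15
    icv_effect: float = -0.05
    f0_intercept: float = 10.25
    f0_lin: float = 0.005
    f0_quad: float = 0.0005
    a0_slack: float = 0.0

    def f0(self, age, female, icv_z):
        """Noise-free normal-aging mean: plateau in youth, accelerating decline."""
        age = np.asarray(age, dtype=float)
        a = age - 16.0
        return (
            self.f0_intercept
            - self.f0_lin * a
            - self.f0_quad * a**2
            + self.sex_effect * np.asarray(female, dtype=float)
            + self.icv_effect * np.asarray(icv_z, dtype=float)
        )

    def excess(self, age, a0):
        """Accumulated excess atrophy (a volume loss, >= 0) after deviation age a0."""
        dt = np.maximum(0.0, np.asarray(age, dtype=float) - a0)
        if self.excess_shape == "linear":
            return self.excess_rate * dt
        if self.excess_shape == "quadratic":
            # smooth-onset ramp: rate grows linearly over 4 y then is constant,
            # so the accumulated loss is a quadratic spline in age
            ramp = 4.0
            return self.excess_rate * np.where(
                dt < ramp, dt**2 / (2 * ramp), dt - ramp / 2.0
            )
        raise ValueError(f"unknown excess_shape {self.excess_shape!r}")


@dataclass
class GroundTruth:
    """Noise-free generating trajectories for a simulated lifespan cohort."""

    config: LifespanConfig
    subjects: pd.DataFrame  # subject_id, group, female, icv_z, a0, intercept_re

    def true_mean(self, subject_id: str, ages) -> np.ndarray:
        """Noise-free population trajectory (random intercept excluded)."""
        row = self.subjects.set_index("subject_id").loc[str(subject_id)]
        base = self.config.f0(ages, row["female"], row["icv_z"])
        if row["group"] == "MS":
            base = base - self.config.excess(ages, row["a0"])
        return np.asarray(base, dtype=float)

    def deviation_ages(self) -> pd.Series:
        ms = self.subjects[self.subjects["group"] == "MS"]
        return ms.set_index("subject_id")["a0"]


def eval_true_mean(config: LifespanConfig, group: str, age, *, female=1.0, icv_z=0.0, a0=None):
    """Noise-free generating mean for one subject profile.

    For controls this is ``f0``; for MS it is ``f0`` before the deviation age
    ``a0`` and ``f0`` minus the accumulated excess atrophy after it (continuous
    at ``a0``).
    """
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 15.0) or np.any(age_arr > 90.0):
        raise ValueError("age outside the supported range [15, 90]")
    base = config.f0(age_arr, female, icv_z)
    if group == "MS":
        if a0 is None:
            raise ValueError("a0 required for MS subjects")
        base = base - config.excess(age_arr, a0)
    elif group != "control":
        raise ValueError(f"unknown group {group!r}")
    return base if np.ndim(age) else float(base)


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Draw from a clipped normal (simple rejection-free clipping)."""
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def generate_lifespan_cohort(config: LifespanConfig, seed: int):
    """Simulate a lifespan cohort; returns ``(ScanTable, GroundTruth)``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    rows = []
    subj_rows = []

    # --- controls -------------------------------------------------------
    counts = np.array([c[0] for c in _CONTROL_AGE_MIXTURE], dtype=float)
    comp = rng.choice(len(counts), size=config.n_controls, p=counts / counts.sum())
    means = np.array([c[1] for c in _CONTROL_AGE_MIXTURE])
    sds = np.array([c[2] for c in _CONTROL_AGE_MIXTURE])
    rep_w = np.array([c[3] for c in _CONTROL_AGE_MIXTURE])
    ages0 = np.clip(rng.normal(means[comp], sds[comp]), 16.0, 88.0)
    female = rng.random(config.n_controls) < config.control_female_fraction
    icv_mean = np.where(female, config.icv_female_mean, config.icv_male_mean)
    icv = np.maximum(rng.normal(icv_mean, config.icv_sd), 8e5)
    icv_z = (icv - 1.475e6) / 1.2e5
    b0 = rng.normal(0.0, config.subject_sd, config.n_controls)
    n_rep = int(round(config.control_repeat_fraction * config.n_controls))
    has_rep = np.zeros(config.n_controls, dtype=bool)
    if n_rep:
        w = rep_w[comp] + 1e-6
        pick = rng.choice(config.n_controls, n_rep, replace=False, p=w / w.sum())
        has_rep[pick] = True

    for i in range(config.n_controls):
        sid = f"HC{i:05d}"
        if has_rep[i]:
            k = int(np.clip(round(rng.normal(config.repeat_scans_mean, config.repeat_scans_sd)), 2, 4))
            span = max(0.5, rng.normal(config.repeat_span_years, config.repeat_span_sd))
            ages = ages0[i] + np.linspace(0.0, span, k)
            ages = ages[ages <= 90.0]
        else:
            ages = np.array([ages0[i]])
        mu = config.f0(ages, female[i], icv_z[i]) + b0[i]
        y = mu + rng.normal(0.0, config.residual_sd, len(ages))
        for a, v in zip(ages, y):
            rows.append((sid, "control", "F" if female[i] else "M", a, icv[i], v * icv[i] / 1000.0, 0.0, 0.0))
        subj_rows.append((sid, "control", float(female[i]), icv_z[i], np.nan, b0[i]))

    # --- MS -------------------------------------------------------------
    onset = np.round(_truncnorm(rng, config.onset_mean, config.onset_sd, 18.0, 60.0,
                                config.n_ms), 2)
    if config.common_deviation_age is not None:
        a0 = np.full(config.n_ms, float(config.common_deviation_age))
        onset = np.maximum(onset, a0 - config.a0_slack)
    else:
        gap = np.maximum(rng.normal(config.gap_mean, config.gap_sd, config.n_ms), 0.0)
        a0 = np.maximum(onset - gap, 16.0)
    entry = onset + np.maximum(rng.normal(config.entry_gap_mean, config.entry_gap_sd, config.n_ms), 0.5)
    entry = np.clip(entry, 18.0, 80.0)
    onset = np.minimum(onset, entry)  # onset never after study entry
    female_ms = rng.random(config.n_ms) < config.ms_female_fraction
    icv_mean = np.where(female_ms, config.icv_female_mean, config.icv_male_mean)
    icv_ms = np.maximum(rng.normal(icv_mean, config.icv_sd), 8e5)
    icv_z_ms = (icv_ms - 1.475e6) / 1.2e5
    b0_ms = rng.normal(0.0, config.subject_sd, config.n_ms)
    dmt = np.round(np.minimum(rng.exponential(2.5, config.n_ms), 15.0), 2)

    for i in range(config.n_ms):
        sid = f"MS{i:05d}"
        k = int(np.clip(round(rng.normal(config.ms_scans_mean, config.ms_scans_sd)), 2, 8))
        ages = entry[i] + np.arange(k, dtype=float)
        ages = ages[ages <= 90.0]
        mu = config.f0(ages, female_ms[i], icv_z_ms[i]) - config.excess(ages, a0[i]) + b0_ms[i]
        y = mu + rng.normal(0.0, config.residual_sd, len(ages))
        for a, v in zip(ages, y):
            rows.append(
                (sid, "MS", "F" if female_ms[i] else "M", a, icv_ms[i], v * icv_ms[i] / 1000.0,
                 float(onset[i]), float(dmt[i]))
            )
        subj_rows.append((sid, "MS", float(female_ms[i]), icv_z_ms[i], float(a0[i]), b0_ms[i]))

    frame = pd.DataFrame(
        rows,
        columns=["subject_id", "group", "sex", "age_at_scan", "icv_mm3", "thalamus_mm3",
                 "clinical_onset_age", "dmt0_years"],
    )
    frame["source"] = "synthetic-lifespan"
    table = build_scan_table(frame)
    truth = GroundTruth(
        config,
        pd.DataFrame(subj_rows, columns=["subject_id", "group", "female", "icv_z", "a0", "intercept_re"]),
    )
    return table, truth


# ----------------------------------------------------------------------
# fish-bone simulation design
# ----------------------------------------------------------------------

@dataclass
class FishboneConfig:
    """Block mixed-model design bending a lifespan backbone into a spline.

    ``schedule`` gives the percent decrease of the intercept/slope weights from
    one block to the next, small in young blocks, larger mid-life, small again
    in old age (default 1% / 5% / 1%).
    """

    n_blocks: int = 10
    age_start: float = 30.0
    block_width: float = 5.0
    subjects_per_block: int = 50
    timepoints: int = 5
    beta00: float = 10.0
    beta10: float = -0.05
    beta01: float = -0.3
    beta11: float = -0.02
    schedule: tuple = (1.0, 5.0, 1.0)  # percent decrease: young / middle / old
    intercept_sd: float = 0.6
    slope_sd: float = 0.05
    re_corr: float = 0.0
    sigma: float = 0.3
    ms_fraction: float = 0.5
    icv: float = 1.5e6
    n_test_subjects: int = 50
    test_extra_ages: tuple = (26.0, 27.0, 28.0, 29.0)

    def weights(self):
        """(W_k, V_k): multiplicative percent decrements in three phases."""
        n = self.n_blocks
        third = n // 3
        pct = np.empty(n - 1)
        pct[: third - 0] = self.schedule[0]
        pct[third : n - 1 - third] = self.schedule[1]
        pct[n - 1 - third :] = self.schedule[2]
        w = np.concatenate([[1.0], np.cumprod(1.0 - pct / 100.0)])
        return w, w.copy()

    def re_cov(self):
        c = self.re_corr * self.intercept_sd * self.slope_sd
        cov = np.array([[self.intercept_sd**2, c], [c, self.slope_sd**2]])
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("random-effect covariance is not PSD")
        return cov


def _fishbone_rows(config, rng, subject_block_iter):
    """Shared generative core.

    ``subject_block_iter`` yields ``(sid, is_ms, block_k, years)`` with Year
    measured within block (0-based; negative for extrapolation ages).
    """
    W, V = config.weights()
    rows = []
    for sid, is_ms, re_b, k, years in subject_block_iter:
        years = np.asarray(years, dtype=float)
        age = config.age_start + config.block_width * k + years
        mean = (
            W[k] * config.beta00
            + V[k] * config.beta10 * years
            + config.beta01 * is_ms
            + config.beta11 * is_ms * years
        )
        y = mean + re_b[0] + re_b[1] * years + rng.normal(0.0, config.sigma, len(years))
        grp = "MS" if is_ms else "control"
        for a, v in zip(age, y):
            rows.append((sid, grp, "F", a, config.icv, v * config.icv / 1000.0,
                         round(float(age.min()), 2) if is_ms else 0.0, 0.0))
    return rows


def _to_table(rows, source):
    frame = pd.DataFrame(
        rows,
        columns=["subject_id", "group", "sex", "age_at_scan", "icv_mm3", "thalamus_mm3",
                 "clinical_onset_age", "dmt0_years"],
    )
    frame["source"] = source
    return build_scan_table(frame)


def generate_fishbone_training(config: FishboneConfig, seed: int) -> ScanTable:
    """Training design: per block, fresh subjects with short rib-bone series.

    Under defaults: 10 blocks x 50 subjects x 5 annual points = 2500 records
    from 500 distinct subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    cov = config.re_cov()
    chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
    n_ms = int(round(config.ms_fraction * config.subjects_per_block))
    years = np.arange(config.timepoints, dtype=float)

    def it():
        for k in range(config.n_blocks):
            for j in range(config.subjects_per_block):
                sid = f"FB{k:02d}S{j:03d}"
                is_ms = 1.0 if j >= config.subjects_per_block - n_ms else 0.0
                re_b = chol @ rng.standard_normal(2)
                yield sid, is_ms, re_b, k, years

    return _to_table(_fishbone_rows(config, rng, it()), "fishbone-train")


def generate_fishbone_testing(config: FishboneConfig, seed: int) -> ScanTable:
    """Testing design: the same subject persists across every block.

    Each subject is observed at all block ages (n_blocks x timepoints = 50
    under defaults) plus the younger extrapolation ages (26-29, generated as
    negative within-block years of the first block), 54 ages in total.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    cov = config.re_cov()
    chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
    years = np.arange(config.timepoints, dtype=float)
    extra = np.asarray(config.test_extra_ages, dtype=float) - config.age_start

    def it():
        for j in range(config.n_test_subjects):
            sid = f"FT{j:03d}"
            re_b = chol @ rng.standard_normal(2)
            yield sid, 1.0, re_b, 0, np.concatenate([extra, years])
            for k in range(1, config.n_blocks):
                yield sid, 1.0, re_b, k, years

    return _to_table(_fishbone_rows(config, rng, it()), "fishbone-test")


def fishbone_true_mean(config: FishboneConfig, block_k: int, year, is_ms: float = 0.0):
    """Noise-free fixed-effect line of one block (oracle for recovery tests)."""
    W, V = config.weights()
    year = np.asarray(year, dtype=float)
    return (
        W[block_k] * config.beta00
        + V[block_k] * config.beta10 * year
        + config.beta01 * is_ms
        + config.beta11 * is_ms * year
    )
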