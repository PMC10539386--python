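import numpy as np
import pandas as pd
import pytest

import atrophytwin as at
from atrophytwin.bases import SplineSpec
from atrophytwin.mixed import CovariateStructure


@pytest.fixture(scope="session")
def lifespan_small():
    """Small lifespan cohort with a common deviation age of 28 years."""
    cfg = at.LifespanConfig(n_controls=150, n_ms=60, common_deviation_age=28.0)
    table, truth = at.generate_lifespan_cohort(cfg, seed=7)
    return cfg, table, truth


@pytest.fixture(scope="session")
def fishbone_small():
    cfg = at.FishboneConfig(subjects_per_block=10)
    return cfg, at.generate_fishbone_training(cfg, seed=11)


@pytest.fixture(scope="session")
def small_fit(lifespan_small):
    """A fitted mixed spline model shared across read-only tests."""
    _, table, _ = lifespan_small
    structure = CovariateStructure("sex_ms", (("sex", frozenset({"main", "ms"})),))
    model = at.MixedSplineModel(table, SplineSpec("cubic_bspline", "toep1", 10), structure)
    return model.fit("ML")


def make_scan_frame(rows):
    """Helper: raw scan frame from (sid, group, sex, age, icv, thal, onset, dmt)."""
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "sex", "age_at_scan", "icv_mm3",
                 "thalamus_mm3", "clinical_onset_age", "dmt0_years"],
    )
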