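"""Agreement statistics: ICC(A,1), repeated-measures correlation, Bland-Altman.

ICC is the single-measure two-way absolute-agreement intraclass correlation
(McGraw-Wong A,1); rmcorr is the common within-subject correlation from the
ANCOVA formulation with subject as a factor.  Both delegate to pingouin; the
test suite checks them against textbook mean-squares arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int


@dataclass
class RmCorrResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    dof: int


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def icc_absolute_agreement(pairs: pd.DataFrame, *, subject="subject", rater="rater",
                           value="value") -> IccResult:
    """ICC(A,1) with its 95% CI from a long table of (subject, rater, value).

    Requires exactly two raters (e.g. observed vs model-augmented) and at
    least five subjects rated by both.
    """
    raters = pairs[rater].unique()
    if len(raters) != 2:
        raise ValueError("exactly 2 raters required")
    wide = pairs.pivot_table(index=subject, columns=rater, values=value).dropna()
    if len(wide) < 5:
        raise ValueError("need >= 5 complete subjects")
    long = wide.reset_index().melt(id_vars=subject, var_name=rater, value_name=value)
    res = pg.intraclass_corr(long, targets=subject, raters=rater, ratings=value)
    row = res.set_index("Type").loc["ICC(A,1)"]
    lo, hi = row["CI95"]
    return IccResult(float(row["ICC"]), float(lo), float(hi), len(wide))


def rmcorr(table: pd.DataFrame, *, subject="subject", x="x", y="y") -> RmCorrResult:
    """Repeated-measures correlation with Fisher-z CI and p value.

    Subjects contributing fewer than two rows are dropped (they carry no
    within-subject information); at least three usable subjects are required.
    """
    counts = table.groupby(subject).size()
    good = counts[counts >= 2].index
    sub = table[table[subject].isin(good)]
    if sub[subject].nunique() < 3:
        raise ValueError("need >= 3 subjects with >= 2 observations")
    res = pg.rm_corr(sub, x=x, y=y, subject=subject)
    lo, hi = res.at["rm_corr", "CI95"]
    return RmCorrResult(
        float(res.at["rm_corr", "r"]),
        float(lo),
        float(hi),
        float(res.at["rm_corr", "pval"]),
        int(res.at["rm_corr", "dof"]),
    )


def bland_altman(a, b) -> BlandAltman:
    """Limits of agreement for paired measurements: mean(d) +- 1.96 sd(d)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    d = a - b
    m = float(d.mean())
    s = float(d.std(ddof=1))
    return BlandAltman(m, s, m - 1.96 * s, m + 1.96 * s, a.size)
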