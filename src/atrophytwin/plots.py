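"""Figures: trajectory pairs, per-patient forest plot, Bland-Altman."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_trajectory_pair(pair, estimate=None, observed=None, ax=None):
    """MS vs twin curves with bands; optionally the PBTL onset CI and scans."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(pair.ages, pair.twin, color="tab:blue", label="healthy twin")
    ax.fill_between(pair.ages, pair.twin_lo, pair.twin_hi, color="tab:blue", alpha=0.15)
    ax.plot(pair.ages, pair.ms, color="goldenrod", label="MS trajectory")
    ax.fill_between(pair.ages, pair.ms_lo, pair.ms_hi, color="goldenrod", alpha=0.15)
    if observed is not None:
        ax.plot(observed[0], observed[1], "kd", ms=5, label="observed scans")
    if estimate is not None and np.isfinite(estimate.pbtl_age):
        ax.errorbar([estimate.pbtl_age], [np.interp(estimate.pbtl_age, pair.ages, pair.twin)],
                    xerr=[[estimate.pbtl_age - estimate.ci_low],
                          [estimate.ci_high - estimate.pbtl_age]],
                    fmt="o", color="green", label="PBTL onset (95% CI)")
        if estimate.clinical_onset_age > 0:
            ax.axvline(estimate.clinical_onset_age, color="red", ls=":", lw=1,
                       label="clinical onset")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("normalized thalamic volume")
    ax.legend(fontsize=8)
    return ax


def plot_onset_forest(onsets, ax=None):
    """Per-patient PBTL-minus-clinical gaps with CIs against the zero line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.12 * len(onsets) + 1.5))
    df = onsets.sort_values("gap").reset_index(drop=True)
    y = np.arange(len(df))
    center = df["pbtl_age"] - df["clinical_onset"]
    lo = df["ci_low"] - df["clinical_onset"]
    hi = df["ci_high"] - df["clinical_onset"]
    colors = np.where(df["label"] == "earlier", "tab:blue", "tab:gray")
    ax.hlines(y, lo, hi, color=colors, lw=0.8)
    ax.plot(center, y, "|", color="black", ms=4)
    ax.axvline(0.0, color="red", lw=1)
    ax.set_xlabel("PBTL onset minus clinical onset (years)")
    ax.set_yticks([])
    return ax


def plot_bland_altman(onsets, label=None, ax=None):
    """Scatter of gaps vs means with the limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    df = onsets if label is None else onsets[onsets["label"] == label]
    a = df["pbtl_age"].to_numpy()
    b = df["clinical_onset"].to_numpy()
    d = a - b
    m = (a + b) / 2.0
    ax.plot(m, d, "o", ms=3, alpha=0.6)
    mu, sd = d.mean(), d.std(ddof=1)
    for v, ls in ((mu, "-"), (mu - 1.96 * sd, "--"), (mu + 1.96 * sd, "--")):
        ax.axhline(v, color="tab:gray", ls=ls, lw=1)
    ax.axhline(0.0, color="red", lw=1)
    ax.set_xlabel("mean of PBTL and clinical onset (years)")
    ax.set_ylabel("PBTL minus clinical onset (years)")
    if label:
        ax.set_title(f"{label} onset")
    return ax
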