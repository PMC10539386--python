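"""Multivariate adaptive regression splines (forward hinge search + GCV pruning).

Used for the cross-sectional normal-aging fit of normalized thalamic volume on
age x ICV x sex.  The model is a sum of products of hinge functions
``max(0, x - c)`` / ``max(0, c - x)`` and linear/indicator factors, grown
greedily in reflected pairs and pruned backwards to minimize the generalized
cross-validation score

    GCV = (RSS / n) / (1 - C(M)/n)^2,   C(M) = #basis functions + d * #knots

with knot penalty ``d`` = 3 when interactions are allowed (2 for additive
models).  Fitting is deterministic given the data: knot candidates are
observed values on a fixed stride, and ties break on first encounter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Factor:
    var: str
    kind: str  # "hinge+", "hinge-", "linear"
    knot: float | None = None

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "linear":
            return x
        if self.kind == "hinge+":
            return np.maximum(0.0, x - self.knot)
        if self.kind == "hinge-":
            return np.maximum(0.0, self.knot - x)
        raise ValueError(self.kind)


@dataclass(frozen=True)
class HingeTerm:
    """Product of factors; the intercept is the empty product."""

    factors: tuple = ()

    @property
    def degree(self) -> int:
        return len(self.factors)

    def variables(self):
        return {f.var for f in self.factors}

    def evaluate(self, data: dict) -> np.ndarray:
        n = len(next(iter(data.values())))
        col = np.ones(n)
        for f in self.factors:
            col = col * f.evaluate(data[f.var])
        return col

    def describe(self) -> str:
        if not self.factors:
            return "1"
        parts = []
        for f in self.factors:
            if f.kind == "linear":
                parts.append(f.var)
            else:
                s = f"{f.var}-{f.knot:g}" if f.kind == "hinge+" else f"{f.knot:g}-{f.var}"
                parts.append(f"max(0,{s})")
        return "*".join(parts)


class AdaptiveSpline:
    """MARS model builder.

    Parameters
    ----------
    y : array
        Response (normalized thalamic volume for the normal-aging fit).
    X : pandas.DataFrame
        Numeric predictors.  Columns with at most two distinct values are
        treated as indicators (linear factors only, no hinges).
    max_degree : int
        Maximum interaction degree (default 3: age x ICV x sex three-way).
    max_terms : int
        Forward-pass budget of basis functions including the intercept.
    knot_stride : int or None
        Candidate knots are every ``stride``-th sorted distinct value; the
        default ``ceil(n/100)`` bounds the forward search.
    penalty : float
        GCV cost per knot (3 with interactions, use 2 for additive fits).
    """

    def __init__(self, y, X: pd.DataFrame, *, max_degree: int = 3, max_terms: int = 21,
                 knot_stride: int | None = None, penalty: float = 3.0):
        if max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        self.data = {c: np.asarray(X[c], dtype=float) for c in X.columns}
        if any(len(v) != n for v in self.data.values()):
            raise ValueError("X and y length mismatch")
        self.max_degree = int(max_degree)
        self.max_terms = int(max_terms)
        self.penalty = float(penalty)
        stride = knot_stride if knot_stride is not None else max(1, int(np.ceil(n / 100)))
        self.knots = {}
        self.binary = {}
        for v, x in self.data.items():
            u = np.unique(x)
            self.binary[v] = len(u) <= 2
            self.knots[v] = u[::stride] if not self.binary[v] else np.array([])

    # -- forward pass -----------------------------------------------------
    def _forward(self):
        y = self.y
        n = len(y)
        terms = [HingeTerm()]
        B = np.ones((n, 1))
        tss = float(((y - y.mean()) ** 2).sum())
        while len(terms) < self.max_terms:
            Q, _ = np.linalg.qr(B)
            resid = y - Q @ (Q.T @ y)
            rss = float(resid @ resid)
            best = (1e-10 * max(tss, 1.0), None)  # minimum useful reduction
            for p_idx, parent in enumerate(terms):
                if parent.degree >= self.max_degree:
                    continue
                pcol = B[:, p_idx]
                for v, x in self.data.items():
                    if v in parent.variables():
                        continue
                    if self.binary[v]:
                        c = pcol * x
                        c = c - Q @ (Q.T @ c)
                        a = float(c @ c)
                        if a > 1e-10:
                            red = float(c @ resid) ** 2 / a
                            if red > best[0]:
                                best = (red, (p_idx, v, None))
                        continue
                    knots = self.knots[v]
                    Hp = pcol[:, None] * np.maximum(0.0, x[:, None] - knots[None, :])
                    Hm = pcol[:, None] * np.maximum(0.0, knots[None, :] - x[:, None])
                    Hp = Hp - Q @ (Q.T @ Hp)
                    Hm = Hm - Q @ (Q.T @ Hm)
                    a = np.einsum("ij,ij->j", Hp, Hp)
                    d = np.einsum("ij,ij->j", Hm, Hm)
                    b = np.einsum("ij,ij->j", Hp, Hm)
                    u = Hp.T @ resid
                    w = Hm.T @ resid
                    det = a * d - b * b
                    scale = np.maximum(a, 1.0) * np.maximum(d, 1.0)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        red_pair = np.where(det > 1e-12 * scale,
                                            (d * u * u - 2 * b * u * w + a * w * w) / det, -np.inf)
                        red_p = np.where(a > 1e-10, u * u / a, -np.inf)
                        red_m = np.where(d > 1e-10, w * w / d, -np.inf)
                    red = np.maximum(red_pair, np.maximum(red_p, red_m))
                    j = int(np.argmax(red))
                    if red[j] > best[0]:
                        best = (float(red[j]), (p_idx, v, float(knots[j])))
            if best[1] is None:
                break
            p_idx, v, knot = best[1]
            parent = terms[p_idx]
            new_cols, new_terms = [], []
            if knot is None:
                t = HingeTerm(parent.factors + (Factor(v, "linear"),))
                new_terms, new_cols = [t], [t.evaluate(self.data)]
            else:
                for kind in ("hinge+", "hinge-"):
                    t = HingeTerm(parent.factors + (Factor(v, kind, knot),))
                    col = t.evaluate(self.data)
                    if float(col @ col) > 1e-12:
                        new_terms.append(t)
                        new_cols.append(col)
            if not new_terms:
                break
            terms.extend(new_terms)
            B = np.column_stack([B] + new_cols)
            # stop early if the fit is already numerically exact
            Q, _ = np.linalg.qr(B)
            r = y - Q @ (Q.T @ y)
            if float(r @ r) <= 1e-12 * max(tss, 1.0):
                break
        return terms, B

    def _gcv(self, rss: float, terms) -> float:
        n = len(self.y)
        n_knots = len({(f.var, f.knot) for t in terms for f in t.factors if f.knot is not None})
        c = len(terms) + self.penalty * n_knots
        if c >= n:
            return np.inf
        return (rss / n) / (1.0 - c / n) ** 2

    # -- backward pass ----------------------------------------------------
    def fit(self) -> "AdaptiveSplineResults":
        terms, B = self._forward()
        y = self.y

        def rss_of(idx):
            coef, res, rank, _ = np.linalg.lstsq(B[:, idx], y, rcond=None)
            r = y - B[:, idx] @ coef
            return float(r @ r), coef

        current = list(range(len(terms)))
        rss, coef = rss_of(current)
        best = (self._gcv(rss, [terms[i] for i in current]), list(current))
        forward_gcv = best[0]
        while len(current) > 1:
            trial_best = None
            for drop in current[1:]:  # never drop the intercept
                idx = [i for i in current if i != drop]
                rss_t, _ = rss_of(idx)
                g = self._gcv(rss_t, [terms[i] for i in idx])
                if trial_best is None or g < trial_best[0]:
                    trial_best = (g, idx)
            current = trial_best[1]
            if trial_best[0] < best[0]:
                best = trial_best
        idx = best[1]
        rss, coef = rss_of(idx)
        kept = [terms[i] for i in idx]
        return AdaptiveSplineResults(
            terms=kept,
            coef=np.asarray(coef, dtype=float),
            gcv=self._gcv(rss, kept),
            gcv_forward=forward_gcv,
            rss=rss,
            n_obs=len(y),
            penalty=self.penalty,
        )


@dataclass
class AdaptiveSplineResults:
    """Pruned MARS model: basis terms, coefficients and the GCV audit trail."""

    terms: list
    coef: np.ndarray
    gcv: float
    gcv_forward: float
    rss: float
    n_obs: int
    penalty: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        data = {c: np.asarray(X[c], dtype=float) for c in X.columns}
        cols = [t.evaluate(data) for t in self.terms]
        return np.column_stack(cols) @ self.coef

    def summary(self) -> str:
        lines = [f"Adaptive spline: {len(self.terms)} basis functions, "
                 f"GCV {self.gcv:.6g} (forward {self.gcv_forward:.6g})"]
        for t, c in zip(self.terms, self.coef):
            lines.append(f"  {c:+.6g} * {t.describe()}")
        return "\n".join(lines)

    # -- JSON serialization ------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "coef": self.coef.tolist(),
            "terms": [[(f.var, f.kind, f.knot) for f in t.factors] for t in self.terms],
            "gcv": self.gcv,
            "gcv_forward": self.gcv_forward,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "penalty": self.penalty,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "AdaptiveSplineResults":
        p = json.loads(text)
        terms = [HingeTerm(tuple(Factor(v, k, kn) for v, k, kn in t)) for t in p["terms"]]
        return cls(terms, np.asarray(p["coef"]), p["gcv"], p["gcv_forward"], p["rss"],
                   p["n_obs"], p["penalty"])


# -- ScanTable-facing wrappers -------------------------------------------

def _control_design(table) -> tuple[np.ndarray, pd.DataFrame]:
    scans = table.scans
    if (scans["group"] != "control").any():
        raise ValueError("cross-sectional normal-aging fit expects controls only")
    X = pd.DataFrame(
        {
            "age": scans["age_at_scan"].to_numpy(),
            "icv": scans["icv_mm3"].to_numpy(),
            "sex": (scans["sex"] == "F").astype(float).to_numpy(),
        }
    )
    return scans["norm_thalamus"].to_numpy(), X


def fit_adaptive_spline(table, *, max_degree: int = 3, max_terms: int = 21,
                        knot_stride: int | None = None, penalty: float = 3.0):
    """Fit the cross-sectional age x ICV x sex MARS model on a control table."""
    y, X = _control_design(table)
    if len(y) < 50:
        raise ValueError("need >= 50 control scans")
    return AdaptiveSpline(y, X, max_degree=max_degree, max_terms=max_terms,
                          knot_stride=knot_stride, penalty=penalty).fit()


def predict_adaptive(model: AdaptiveSplineResults, age, icv, sex) -> np.ndarray:
    """Vectorized prediction; ``sex`` accepts "F"/"M" or a 0/1 indicator."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    icv = np.broadcast_to(np.atleast_1d(np.asarray(icv, dtype=float)), age.shape)
    if isinstance(sex, str):
        if sex not in ("F", "M"):
            raise ValueError(f"unknown sex level {sex!r}")
        sex_ind = 1.0 if sex == "F" else 0.0
    else:
        sex_ind = sex
    sex_col = np.broadcast_to(np.atleast_1d(np.asarray(sex_ind, dtype=float)), age.shape)
    X = pd.DataFrame({"age": age, "icv": icv, "sex": sex_col})
    return model.predict(X)
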