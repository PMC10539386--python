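"""Spline bases and smoothing-penalty structures for the mixed spline model.

Four bases (cubic B-spline, cubic truncated power function, and their natural
restricted variants) crossed with three G-side penalty types (TOEP(1) ridge,
P-spline adjacent-difference penalty, radial smoothing) give the twelve
candidate structures.  Every structure is reduced to the same mixed-model
canonical form: a fixed polynomial part ``F`` plus a penalized block ``Z``
whose coefficients are iid ``N(0, tau^2)`` after an exact linear
reparameterization of the penalty.

Numerical conventions
---------------------
* Ages are affinely mapped to ``s in [0, 1]`` over the training range before
  any basis is built, so penalized-column magnitudes are O(1).
* The truncated power block is kept in its raw per-knot coordinates (the
  ridge there is the classic "random TPF coefficients" smoother), while the
  B-spline block is the polynomial-orthogonal residual of the B-spline design
  in native knot order — the two bases deliberately smooth in different
  coordinate systems and can fit differently.
* Both natural variants (TPF-restricted and boundary-constrained B-spline)
  span the same function space; their penalized blocks are standardized to the
  age-weighted canonical orthonormal basis of that span, so the two
  parameterizations yield numerically identical fits.
* The P-spline penalty's null direction (a constant shift of adjacent
  coefficients) is not a proper random effect and is constrained to zero,
  keeping the fixed part identical across penalty types.
* Radial smoothing replaces the penalized block by ``|s - t_j|^3`` columns
  scaled by ``Omega^{-1/2}``, ``Omega_jk = |t_j - t_k|^3``; the basis enum
  then only controls the fixed polynomial part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

BASES = ("cubic_bspline", "cubic_tpf", "natural_bspline", "natural_tpf")
PENALTIES = ("toep1", "pspline", "rsmooth")

_SV_RTOL = 1e-9


@dataclass(frozen=True)
class SplineSpec:
    """One basis/penalty structure with its knot configuration."""

    basis: str
    penalty: str
    n_knots: int = 15

    def __post_init__(self):
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.penalty not in PENALTIES:
            raise ValueError(f"unknown penalty {self.penalty!r}")

    @property
    def id(self) -> str:
        return f"{self.basis}+{self.penalty}"


def default_knots(s: np.ndarray, n_knots: int) -> np.ndarray:
    """Interior knots at quantiles of the scaled ages, capped by data support."""
    n_distinct = len(np.unique(s))
    k = int(min(n_knots, max(3, n_distinct // 4), 35))
    q = np.arange(1, k + 1) / (k + 1)
    knots = np.unique(np.quantile(np.unique(s), q))
    if len(knots) < 3:
        raise ValueError("fewer than 3 distinct interior knots available")
    return knots


def _poly(s: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(s, degree + 1, increasing=True)


def _tpf3(s: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, s[:, None] - knots[None, :]) ** 3


def _bspline_design(s: np.ndarray, knots: np.ndarray) -> np.ndarray:
    t = np.concatenate([[0.0] * 4, knots, [1.0] * 4])
    return BSpline.design_matrix(s, t, 3, extrapolate=True).toarray()


def _natural_tpf_raw(s: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline columns (linear beyond the boundary knots)."""
    t = knots
    K = len(t)
    tk, tk1 = t[-1], t[-2]
    cols = []
    for j in range(K - 2):
        d = (
            np.maximum(0.0, s - t[j]) ** 3
            - np.maximum(0.0, s - tk1) ** 3 * (tk - t[j]) / (tk - tk1)
            + np.maximum(0.0, s - tk) ** 3 * (tk1 - t[j]) / (tk - tk1)
        )
        cols.append(d)
    return np.column_stack(cols)


def _natural_bspline_raw(s: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic B-splines constrained to vanishing 2nd/3rd derivatives at 0 and 1.

    With the same interior knots this spans the space of splines that are
    linear outside [t_1, t_K] — the natural spline space of the TPF-restricted
    construction — parameterized through B-spline coefficients instead.
    """
    t = np.concatenate([[0.0] * 4, knots, [1.0] * 4])
    ncoef = len(knots) + 4
    cons = []
    for x0 in (0.0, 1.0):
        for nu in (2, 3):
            row = np.zeros(ncoef)
            for i in range(ncoef):
                c = np.zeros(ncoef)
                c[i] = 1.0
                row[i] = BSpline(t, c, 3, extrapolate=True).derivative(nu)(x0)
            cons.append(row)
    C = np.vstack(cons)
    _, sv, vt = np.linalg.svd(C)
    null = vt[np.sum(sv > 1e-10 * sv[0]) :].T  # ncoef x (ncoef - 4)
    return _bspline_design(s, knots) @ null


def _sign_fix(train_cols: np.ndarray, transform: np.ndarray):
    """Deterministic column signs: largest-|entry| training value positive."""
    idx = np.argmax(np.abs(train_cols), axis=0)
    signs = np.sign(train_cols[idx, np.arange(train_cols.shape[1])])
    signs[signs == 0] = 1.0
    return train_cols * signs, transform * signs


class BasisBuilder:
    """Fit basis transforms on training ages; evaluate on arbitrary grids.

    ``fit`` freezes the age scaling, knots and every reparameterization
    matrix; ``transform`` then reproduces the training columns exactly and
    extends them smoothly (linearly, for natural bases) outside the range.
    """

    def __init__(self, spec: SplineSpec):
        self.spec = spec
        self._fitted = False

    # -- construction ------------------------------------------------------
    def fit(self, ages, knots=None) -> "BasisBuilder":
        ages = np.asarray(ages, dtype=float)
        if len(np.unique(ages)) < 4:
            raise ValueError("need >= 4 distinct ages for a cubic basis")
        self.a_min = float(ages.min())
        self.a_max = float(ages.max())
        if self.a_max <= self.a_min:
            raise ValueError("degenerate age range")
        s = self._scale(ages)
        if knots is None:
            self.knots = default_knots(s, self.spec.n_knots)
        else:
            knots = np.asarray(knots, dtype=float)
            if np.any(knots <= 0) or np.any(knots >= 1) or np.any(np.diff(knots) <= 0):
                raise ValueError("knots must be strictly increasing inside the age range")
            self.knots = knots

        basis = self.spec.basis
        self.fixed_degree = 3 if basis.startswith("cubic") else 1
        F = _poly(s, self.fixed_degree)

        if self.spec.penalty == "rsmooth":
            self._fit_rsmooth()
        elif basis == "cubic_tpf":
            self._proj = None
            self._post = np.eye(len(self.knots))
        elif basis == "cubic_bspline":
            # penalized block = B-spline columns with the polynomial part
            # projected out, kept in native knot order (rank K, K+4 columns);
            # the ridge / difference penalty acts on B-spline coefficients
            raw = _bspline_design(s, self.knots)
            A, *_ = np.linalg.lstsq(F, raw, rcond=None)
            self._proj = A
            self._post = np.eye(raw.shape[1])
        else:  # natural variants: canonical age-weighted basis of the shared span
            raw = (_natural_tpf_raw if basis == "natural_tpf" else _natural_bspline_raw)(
                s, self.knots
            )
            self._fit_canonical(F, raw, s, rank=len(self.knots) - 2, weighted=True)

        if self.spec.penalty == "pspline":
            self._post = self._post @ _difference_reparam(self._post.shape[1])
        self._fitted = True
        return self

    def _fit_canonical(self, F, raw, s, rank, weighted):
        A, *_ = np.linalg.lstsq(F, raw, rcond=None)
        R = raw - F @ A
        u, sv, vt = np.linalg.svd(R, full_matrices=False)
        keep = min(rank, int(np.sum(sv > _SV_RTOL * sv[0])))
        post = vt[:keep].T / sv[:keep]
        U = R @ post  # orthonormal training columns
        if weighted:
            T = U.T @ (s[:, None] * U)
            w, E = np.linalg.eigh((T + T.T) / 2.0)
            post = post @ E
            U = R @ post
        U, post = _sign_fix(U, post)
        self._proj = A
        self._post = post

    def _fit_rsmooth(self):
        t = self.knots
        omega = np.abs(t[:, None] - t[None, :]) ** 3
        w, E = np.linalg.eigh((omega + omega.T) / 2.0)
        good = np.abs(w) > 1e-12 * np.abs(w).max()
        self._post = (E[:, good] / np.sqrt(np.abs(w[good]))) @ E[:, good].T
        self._proj = None

    # -- evaluation --------------------------------------------------------
    def _scale(self, ages):
        return (np.asarray(ages, dtype=float) - self.a_min) / (self.a_max - self.a_min)

    def _raw(self, s):
        basis, penalty = self.spec.basis, self.spec.penalty
        if penalty == "rsmooth":
            return np.abs(s[:, None] - self.knots[None, :]) ** 3
        if basis == "cubic_tpf":
            return _tpf3(s, self.knots)
        if basis == "cubic_bspline":
            return _bspline_design(s, self.knots)
        if basis == "natural_tpf":
            return _natural_tpf_raw(s, self.knots)
        return _natural_bspline_raw(s, self.knots)

    def transform(self, ages):
        """Evaluate ``(F, Z)`` — fixed polynomial part and penalized block."""
        if not self._fitted:
            raise RuntimeError("BasisBuilder.fit must be called first")
        s = self._scale(ages)
        F = _poly(s, self.fixed_degree)
        raw = self._raw(s)
        if self._proj is not None:
            raw = raw - F[:, : self._proj.shape[0]] @ self._proj
        return F, raw @ self._post

    def transform_local(self, ages) -> np.ndarray:
        """Penalized block for group/covariate interaction smooths.

        For the cubic B-spline basis this is the raw (unprojected) local
        B-spline design: every column has compact support, so a difference
        smooth fitted only where one group has data shrinks to zero outside
        that support instead of extrapolating a global polynomial residual.
        Other bases return the same block as :meth:`transform`.
        """
        if not self._fitted:
            raise RuntimeError("BasisBuilder.fit must be called first")
        if self.spec.basis == "cubic_bspline" and self.spec.penalty != "rsmooth":
            raw = _bspline_design(self._scale(ages), self.knots)
            return raw @ self._post
        return self.transform(ages)[1]

    @property
    def n_penalized(self) -> int:
        return self._post.shape[1]


def _difference_reparam(k: int) -> np.ndarray:
    """Exact reparameterization of the first-difference penalty to iid form.

    For coefficients b with penalty ``b' D'D b`` (D the first-difference
    operator) the positive-eigenvalue directions are rescaled to unit penalty;
    the null direction (constant) is constrained to zero.
    """
    if k < 2:
        return np.eye(k)
    D = np.diff(np.eye(k), axis=0)
    w, E = np.linalg.eigh(D.T @ D)
    good = w > 1e-10 * w.max()
    return E[:, good] / np.sqrt(w[good])


def build_spline_basis(ages, spec: SplineSpec, knots=None):
    """Convenience wrapper: fit on ``ages`` and return ``(F, Z)`` there."""
    return BasisBuilder(spec).fit(ages, knots=knots).transform(ages)
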