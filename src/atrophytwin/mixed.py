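"""Penalized spline mixed models for combined control + MS longitudinal tables.

Model
-----
For scan j of subject i at age t::

    Y_ij = mu(t) + mu_MS(t) * MS_i + X_ij beta + u_i + eps_ij

where ``mu`` and the MS-specific departure ``mu_MS`` are penalized splines
(fixed polynomial part + penalized basis block with iid N(0, tau^2)
coefficients after the penalty reparameterization — the mixed-model form of
spline smoothing, so the smoothing parameter is a variance ratio estimated by
ML/REML), ``X_ij`` holds the covariate structure, ``u_i`` is a subject random
intercept (optionally + slope) and ``eps ~ N(0, sigma^2)``.

Fitting profiles the likelihood over variance ratios
``lambda = tau^2/sigma^2`` (one shared smoothing ratio for all penalized
blocks) and the subject ratio(s), using Woodbury identities: subject blocks
are rank-1/2 and inverted in closed form, the global spline block is low rank.
A single likelihood evaluation costs O(m * c^2 + c^3) for m subjects and c
design columns after one-time cross-product precomputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .bases import BasisBuilder, SplineSpec
from .cohort import ScanTable

#: covariates available to the structure catalog (canonical order)
COVARIATES = ("sex", "thalamus0", "icv0", "onset_age", "dmt0", "entry_age")
#: covariates excluded from three-way (covariate x MS x age-spline) terms
NO_THREE_WAY = ("dmt0", "onset_age")
_COMPONENTS = ("main", "ms", "spline", "ms_spline")

_LOG_LAM_BOUND = 14.0


@dataclass(frozen=True)
class CovariateStructure:
    """A bundle-valid covariate structure on top of the mandatory block.

    ``terms`` maps each covariate to its interaction components:
    ``main`` (always required), ``ms`` (x MS status), ``spline`` (x age
    spline) and ``ms_spline`` (x MS x age spline, requiring both two-way
    components — interactions stay intact with their marginals as a bundle).
    The mandatory block {age-spline, MS, age-spline x MS} is implicit.
    """

    name: str
    terms: tuple = ()  # ((covariate, frozenset of components), ...)

    def __post_init__(self):
        seen = set()
        for cov, comps in self.terms:
            if cov not in COVARIATES:
                raise ValueError(f"unknown covariate {cov!r}")
            if cov in seen:
                raise ValueError(f"duplicate covariate {cov!r}")
            seen.add(cov)
            comps = frozenset(comps)
            if not comps <= set(_COMPONENTS):
                raise ValueError(f"unknown components {comps - set(_COMPONENTS)}")
            if "main" not in comps:
                raise ValueError(f"{cov}: the main effect is part of every bundle")
            if "ms_spline" in comps and not {"ms", "spline"} <= comps:
                raise ValueError(f"{cov}: three-way term requires both two-way components")
            if "ms_spline" in comps and cov in NO_THREE_WAY:
                raise ValueError(f"{cov} may not enter a three-way spline term")

    def components(self, cov: str) -> frozenset:
        for c, comps in self.terms:
            if c == cov:
                return frozenset(comps)
        return frozenset()

    @property
    def n_terms(self) -> int:
        return sum(len(c) for _, c in self.terms)


def mandatory_structure() -> CovariateStructure:
    """Age-spline + MS + age-spline x MS only (no extra covariates)."""
    return CovariateStructure("mandatory")


def _patient_covariates(patient) -> dict:
    """Normalize a covariate row / dict to canonical keys."""
    if isinstance(patient, pd.Series):
        patient = patient.to_dict()
    out = dict(patient)
    alias = {"clinical_onset_age": "onset_age", "age_at_entry": "entry_age",
             "dmt0_years": "dmt0"}
    for src, dst in alias.items():
        if src in out and dst not in out:
            out[dst] = out[src]
    if isinstance(out.get("sex"), str):
        out["sex"] = 1.0 if out["sex"] == "F" else 0.0
    return out


class MixedSplineModel:
    """Penalized spline mixed model built from a :class:`ScanTable`.

    Parameters
    ----------
    table : ScanTable
        Combined control + MS longitudinal table (augmented rows welcome).
    spec : SplineSpec
        Basis/penalty structure.
    structure : CovariateStructure, optional
        Covariate structure; defaults to the mandatory block only.
    knots : array, optional
        Interior knots on the scaled age axis (reuse across refits so
        bootstrap replicates share one basis).
    subject_slope : bool
        Add a subject-level random slope in centered age (independent of the
        intercept).  Default is intercept only.
    ms_poly : {"linear", "full"}
        Fixed polynomial part of the MS x age-spline (and covariate x spline)
        interactions.  ``"linear"`` (default) keeps only {group offset, group
        x age} unpenalized and routes all higher-order group-difference
        curvature through the penalized block, so the difference curve
        extrapolates linearly (with shrunk curvature) outside the MS age
        support; ``"full"`` duplicates the whole fixed polynomial, which lets
        an unpenalized cubic group difference extrapolate freely.
    """

    def __init__(self, table: ScanTable, spec: SplineSpec,
                 structure: CovariateStructure | None = None, *,
                 knots=None, basis: BasisBuilder | None = None,
                 subject_slope: bool = False, ms_poly: str = "linear",
                 standardize: dict | None = None,
                 interaction_proj: dict | None = None):
        if ms_poly not in ("linear", "full"):
            raise ValueError("ms_poly must be 'linear' or 'full'")
        self.ms_poly = ms_poly
        self.table = table
        self.spec = spec
        self.structure = structure or mandatory_structure()
        self.subject_slope = bool(subject_slope)

        scans = table.scans.merge(
            table.covariates[["subject_id", "thalamus0", "icv0", "age_at_entry",
                              "clinical_onset_age", "dmt0"]],
            on="subject_id", how="left", suffixes=("", "_cov"),
        )
        scans = scans.sort_values(["subject_id", "age_at_scan"], kind="mergesort")
        self._scans = scans.reset_index(drop=True)
        ages = self._scans["age_at_scan"].to_numpy()
        self.y = self._scans["norm_thalamus"].to_numpy()
        self.n_obs = len(self.y)
        self.ms = (self._scans["group"] == "MS").to_numpy().astype(float)

        if basis is not None:
            self.basis = basis
        else:
            self.basis = BasisBuilder(spec).fit(ages, knots=knots)

        raw_cov = {
            "sex": (self._scans["sex"] == "F").to_numpy().astype(float),
            "thalamus0": self._scans["thalamus0"].to_numpy().astype(float),
            "icv0": self._scans["icv0"].to_numpy().astype(float),
            "onset_age": self._scans["clinical_onset_age"].to_numpy().astype(float),
            "dmt0": self._scans["dmt0"].to_numpy().astype(float),
            "entry_age": self._scans["age_at_entry"].to_numpy().astype(float),
        }
        # continuous covariates standardized by training moments (sex stays 0/1)
        if standardize is None:
            standardize = {}
            for cov in COVARIATES:
                if cov == "sex":
                    standardize[cov] = (0.0, 1.0)
                else:
                    mu = float(np.mean(raw_cov[cov]))
                    sd = float(np.std(raw_cov[cov]))
                    standardize[cov] = (mu, sd if sd > 1e-12 else 1.0)
        self.standardize = standardize
        self._cov = {c: (raw_cov[c] - standardize[c][0]) / standardize[c][1]
                     for c in COVARIATES}

        F, Z0 = self.basis.transform(ages)
        Zi = self.basis.transform_local(ages) if self.ms_poly == "linear" else Z0
        (self.X, self.Z, self.fixed_names, self.penalized_blocks,
         self._interaction_proj) = self._assemble(F, Z0, self.ms, self._cov, Zi,
                                                  proj=interaction_proj)
        self.n_fixed = self.X.shape[1]
        self.n_pen = self.Z.shape[1]

        # subject grouping (rows are sorted by subject)
        sid = self._scans["subject_id"].to_numpy()
        change = np.concatenate([[True], sid[1:] != sid[:-1]])
        self._starts = np.flatnonzero(change)
        self._counts = np.diff(np.concatenate([self._starts, [self.n_obs]]))
        self.subject_ids = sid[self._starts]
        self.n_subjects = len(self._starts)
        self._age_c = ages - ages.mean()

        self._precompute()

    # -- design assembly ---------------------------------------------------
    def _assemble(self, F, Z0, ms, cov, Zi=None, proj=None):
        """Build fixed and penalized design blocks.

        Every interaction smooth block is orthogonalized against its own
        fixed interaction columns (group offset and group x age trend), so
        the unpenalized line carries the full low-order group difference and
        shrinkage of the penalized block cannot bias it — without this, part
        of a linear group trend leaks into the shrunk spline coefficients and
        bows the difference curve at the sparse edges of the group's age
        support.  The projection matrices are estimated on the training rows
        and reused verbatim for prediction (``proj``).
        """
        if Zi is None:
            Zi = Z0
        learn = proj is None
        if learn:
            proj = {}
        fixed_cols, names = [], []
        deg_int = F.shape[1] if self.ms_poly == "full" else min(2, F.shape[1])
        for j in range(F.shape[1]):
            fixed_cols.append(F[:, j])
            names.append(f"age^{j}" if j else "intercept")
        ms_fixed = [ms * F[:, j] for j in range(deg_int)]
        for j, col in enumerate(ms_fixed):
            fixed_cols.append(col)
            names.append("MS" if j == 0 else f"MS:age^{j}")

        def add_block(name, block, G_cols):
            G = np.column_stack(G_cols)
            if learn:
                gtg = G.T @ G
                if np.linalg.cond(gtg) < 1e12:
                    A = np.linalg.solve(gtg, G.T @ block)
                else:
                    A = np.zeros((G.shape[1], block.shape[1]))
                proj[name] = A
            pen_blocks.append((name, block - G @ proj[name]))

        pen_blocks = [("smooth", Z0)]
        add_block("smooth:MS", ms[:, None] * Zi, ms_fixed)
        for c, comps in self.structure.terms:
            x = cov[c]
            names.append(c)
            fixed_cols.append(x)
            if "ms" in comps:
                names.append(f"{c}:MS")
                fixed_cols.append(x * ms)
            if "spline" in comps:
                g_cols = [x * F[:, j] for j in range(deg_int)]
                for j in range(1, deg_int):
                    names.append(f"{c}:age^{j}")
                    fixed_cols.append(g_cols[j])
                add_block(f"smooth:{c}", x[:, None] * Zi, g_cols)
            if "ms_spline" in comps:
                g_cols = [x * ms * F[:, j] for j in range(deg_int)]
                for j in range(1, deg_int):
                    names.append(f"{c}:MS:age^{j}")
                    fixed_cols.append(g_cols[j])
                add_block(f"smooth:{c}:MS", (x * ms)[:, None] * Zi, g_cols)
        X = np.column_stack(fixed_cols)
        Z = np.hstack([b for _, b in pen_blocks])
        return X, Z, names, [name for name, _ in pen_blocks], proj

    # -- likelihood machinery ----------------------------------------------
    def _precompute(self):
        M = np.column_stack([self.X, self.Z, self.y])
        self._M = M
        self._MtM = M.T @ M
        cols = [np.ones(self.n_obs)]
        if self.subject_slope:
            cols.append(self._age_c)
        self._sub_cols = cols
        self._S = np.stack([np.add.reduceat(M * w[:, None], self._starts, axis=0)
                            for w in cols], axis=1)  # (m, r, c)
        # per-subject Gram of the subject random-effect design
        self._G = np.empty((self.n_subjects, len(cols), len(cols)))
        for a, wa in enumerate(cols):
            for b, wb in enumerate(cols):
                self._G[:, a, b] = np.add.reduceat(wa * wb, self._starts)

    @property
    def _r_sub(self) -> int:
        return len(self._sub_cols)

    def _crossprod(self, lam_sub):
        """M' B^{-1} M and log|B| for B_i = I + W_i diag(lam) W_i'."""
        lam = np.asarray(lam_sub, dtype=float)
        r = self._r_sub
        # inv(B_i) correction uses  C_i = (diag(1/lam) + G_i)^{-1}
        # computed stably as  lam^{1/2} (I + lam^{1/2} G lam^{1/2})^{-1} lam^{1/2}
        sq = np.sqrt(lam)
        K = np.eye(r)[None] + (sq[:, None] * self._G * sq[None, :])
        sign, logdet = np.linalg.slogdet(K)
        Ssc = self._S * sq[None, :, None]  # (m, r, c)
        sol = np.linalg.solve(K, Ssc)
        corr = np.einsum("mrc,mrd->cd", Ssc, sol)
        return self._MtM - corr, float(logdet.sum())

    def _neg2ll(self, eta, method):
        eta = np.clip(np.asarray(eta, dtype=float), -_LOG_LAM_BOUND, _LOG_LAM_BOUND)
        lam_s = np.exp(eta[0])
        lam_sub = np.exp(eta[1:])
        C, logdetB = self._crossprod(lam_sub)
        p, K, n = self.n_fixed, self.n_pen, self.n_obs
        Fxx = C[:p, :p]
        Fxz = C[:p, p:p + K]
        fxy = C[:p, -1]
        Szz = C[p:p + K, p:p + K]
        szy = C[p:p + K, -1]
        syy = C[-1, -1]
        A = Szz + np.eye(K) / lam_s
        try:
            cfA = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdetA = 2.0 * np.log(np.diag(cfA[0])).sum()
        logdetW = logdetB + K * np.log(lam_s) + logdetA
        AiZx = cho_solve(cfA, Fxz.T)  # K x p
        Aizy = cho_solve(cfA, szy)
        XtWiX = Fxx - Fxz @ AiZx
        XtWiy = fxy - Fxz @ Aizy
        ytWiy = syy - szy @ Aizy
        XtWiX = (XtWiX + XtWiX.T) / 2.0
        try:
            cfX = cho_factor(XtWiX, lower=True)
        except np.linalg.LinAlgError:
            # near-rank-deficient fixed part: retry with a tiny ridge
            try:
                cfX = cho_factor(
                    XtWiX + 1e-10 * np.eye(p) * max(1.0, np.trace(XtWiX) / p),
                    lower=True)
            except np.linalg.LinAlgError:
                return np.inf, None
        beta = cho_solve(cfX, XtWiy)
        rss = max(ytWiy - beta @ XtWiy, 1e-300)
        if method == "ML":
            sigma2 = rss / n
            val = n * np.log(2 * np.pi * sigma2) + logdetW + n
        else:
            dof = n - p
            sigma2 = rss / dof
            logdetXX = 2.0 * np.log(np.diag(cfX[0])).sum()
            val = dof * np.log(2 * np.pi * sigma2) + logdetW + logdetXX + dof
        aux = dict(beta=beta, sigma2=sigma2, lam_s=lam_s, lam_sub=lam_sub,
                   cfA=cfA, szy=szy, Fxz=Fxz, Szz=Szz, C=C, logdetW=logdetW)
        return float(val), aux

    def fit(self, method: str = "REML", *, fixed_components=None,
            maxiter: int = 400) -> "MixedSplineResults":
        """Estimate variance components by profiled ML/REML and return results.

        ``fixed_components`` skips optimization and evaluates at the given
        variance ratios ``(lam_smooth, lam_subject[, lam_slope])``.
        """
        if method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        n_eta = 1 + self._r_sub
        if fixed_components is not None:
            eta = np.log(np.maximum(np.asarray(fixed_components, dtype=float), 1e-12))
            val, aux = self._neg2ll(eta, method)
            return self._finalize(method, eta, val, aux, converged=True, n_iter=0)

        def obj(eta):
            return self._neg2ll(eta, method)[0]

        opts = dict(maxiter=maxiter, xatol=1e-7, fatol=1e-9)
        res = optimize.minimize(obj, np.zeros(n_eta), method="Nelder-Mead",
                                options=opts)
        # a boundary solution (smoothing variance collapsed or exploded) can
        # be a local basin; retry from fixed alternative starts and keep the
        # best — deterministic, no random restarts
        if np.any(np.abs(res.x) >= _LOG_LAM_BOUND - 0.5):
            for start in ([-4.0] + [1.0] * (n_eta - 1),
                          [4.0] + [1.0] * (n_eta - 1)):
                alt = optimize.minimize(obj, np.asarray(start),
                                        method="Nelder-Mead", options=opts)
                if alt.fun < res.fun - 1e-9:
                    res = alt
        val, aux = self._neg2ll(res.x, method)
        converged = bool(res.success) and bool(np.isfinite(val))
        return self._finalize(method, res.x, val, aux, converged, res.nit)

    def _finalize(self, method, eta, val, aux, converged, n_iter):
        if aux is None:
            raise RuntimeError("likelihood evaluation failed at the optimum")
        p, K = self.n_fixed, self.n_pen
        beta = aux["beta"]
        # BLUPs of the penalized coefficients: u = lam_s Z'W^{-1}(y - X beta)
        zr = aux["szy"] - aux["Fxz"].T @ beta  # Z'B^{-1} r
        u = aux["lam_s"] * (zr - aux["Szz"] @ cho_solve(aux["cfA"], zr))
        sigma2 = aux["sigma2"]
        # joint covariance of (beta, u): sigma^2 (M'B^{-1}M + diag(0, I/lam_s))^{-1}
        H = aux["C"][:p + K, :p + K].copy()
        H[p:, p:] += np.eye(K) / aux["lam_s"]
        H = (H + H.T) / 2.0
        jitter = 1e-10 * max(1.0, np.trace(H) / (p + K))
        cov_joint = sigma2 * np.linalg.inv(H + jitter * np.eye(p + K))
        n_vc = 2 + self._r_sub  # sigma^2, smoothing ratio, subject component(s)
        n_par = p + n_vc
        llf = -0.5 * val
        aic = val + 2 * n_par
        bic = val + n_par * np.log(self.n_obs)
        eta = np.clip(eta, -_LOG_LAM_BOUND, _LOG_LAM_BOUND)
        boundary = bool(np.any(np.abs(eta) >= _LOG_LAM_BOUND - 0.11))
        return MixedSplineResults(
            model=self, method=method, fe_params=beta, blups=u,
            sigma2=float(sigma2), tau2=float(sigma2 * aux["lam_s"]),
            subject_var=tuple(float(sigma2 * l) for l in aux["lam_sub"]),
            lam=(float(aux["lam_s"]), *[float(l) for l in aux["lam_sub"]]),
            llf=float(llf), aic=float(aic), bic=float(bic), n_params=n_par,
            cov_joint=cov_joint, converged=converged, boundary=boundary,
            n_iter=int(n_iter),
        )

    # -- helpers for prediction / bootstrap ---------------------------------
    def design_rows(self, patient, group: str, ages) -> tuple[np.ndarray, np.ndarray]:
        """Fixed and penalized design rows for one covariate profile on a grid."""
        ages = np.asarray(ages, dtype=float)
        pc = _patient_covariates(patient)
        ms_flag = 1.0 if group == "MS" else 0.0
        if group not in ("MS", "control"):
            raise ValueError(f"unknown group {group!r}")
        F, Z0 = self.basis.transform(ages)
        cov = {}
        for c in COVARIATES:
            if self.structure.components(c):
                if c not in pc or pc[c] is None or (isinstance(pc[c], float) and np.isnan(pc[c])):
                    raise ValueError(f"missing covariate {c!r}")
                mu, sd = self.standardize[c]
                cov[c] = np.full(len(ages), (float(pc[c]) - mu) / sd)
            else:
                cov[c] = np.zeros(len(ages))
        ms = np.full(len(ages), ms_flag)
        Zi = self.basis.transform_local(ages) if self.ms_poly == "linear" else Z0
        X, Z, _, _, _ = self._assemble(F, Z0, ms, cov, Zi, proj=self._interaction_proj)
        return X, Z

    def per_subject_crossprods(self, lam_sub) -> np.ndarray:
        """Per-subject contributions A_i to M'B^{-1}M (for the fast bootstrap)."""
        lam = np.asarray(lam_sub, dtype=float)
        r = self._r_sub
        sq = np.sqrt(lam)
        m = self.n_subjects
        c = self._M.shape[1]
        out = np.empty((m, c, c))
        K = np.eye(r)[None] + (sq[:, None] * self._G * sq[None, :])
        Ssc = self._S * sq[None, :, None]
        sol = np.linalg.solve(K, Ssc)
        ends = np.concatenate([self._starts[1:], [self.n_obs]])
        for i in range(m):
            Mi = self._M[self._starts[i]:ends[i]]
            out[i] = Mi.T @ Mi - Ssc[i].T @ sol[i]
        return out


@dataclass
class MixedSplineResults:
    """Fitted penalized spline mixed model.

    ``fe_params`` are the fixed effects (see ``model.fixed_names``), ``blups``
    the predicted penalized spline coefficients, ``tau2`` the smoothing
    variance, ``subject_var`` the subject random-effect variance(s) and
    ``sigma2`` the residual variance.  ``aic``/``bic`` use
    p = n_fixed + n_variance_components under the fitting likelihood.
    """

    model: MixedSplineModel
    method: str
    fe_params: np.ndarray
    blups: np.ndarray
    sigma2: float
    tau2: float
    subject_var: tuple
    lam: tuple
    llf: float
    aic: float
    bic: float
    n_params: int
    cov_joint: np.ndarray
    converged: bool
    boundary: bool
    n_iter: int

    def predict(self, patient, group: str, ages, *, band: bool = True, level: float = 0.95):
        """Population-level trajectory for one covariate profile.

        Returns ``(curve, lo, hi)`` on the age grid (``lo``/``hi`` are the
        pointwise confidence band from the joint fixed + penalized coefficient
        covariance; subject random effects are set to zero).
        """
        X, Z = self.model.design_rows(patient, group, ages)
        curve = X @ self.fe_params + Z @ self.blups
        if not band:
            return curve, None, None
        R = np.column_stack([X, Z])
        var = np.einsum("ij,jk,ik->i", R, self.cov_joint, R)
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(np.maximum(var, 0.0))
        return curve, curve - half, curve + half

    def fitted_values(self) -> np.ndarray:
        return self.model.X @ self.fe_params + self.model.Z @ self.blups

    def predict_scans(self, table: ScanTable) -> np.ndarray:
        """Population predictions at the observed scans of another table."""
        sub = MixedSplineModel(table, self.model.spec, self.model.structure,
                               basis=self.model.basis,
                               standardize=self.model.standardize,
                               subject_slope=self.model.subject_slope,
                               ms_poly=self.model.ms_poly,
                               interaction_proj=self.model._interaction_proj)
        return sub.X @ self.fe_params + sub.Z @ self.blups

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Penalized spline mixed model ({m.spec.id}; structure {m.structure.name})",
            f"  n_obs {m.n_obs}, subjects {m.n_subjects}, fixed {m.n_fixed}, "
            f"penalized {m.n_pen}",
            f"  {self.method} llf {self.llf:.3f}  AIC {self.aic:.2f}  BIC {self.bic:.2f}"
            f"  (p = {self.n_params})",
            f"  sigma^2 {self.sigma2:.5f}  tau^2 {self.tau2:.3g}  "
            f"subject var {tuple(round(v, 5) for v in self.subject_var)}"
            + ("  [boundary]" if self.boundary else "")
            + ("" if self.converged else "  [NOT CONVERGED]"),
            "  fixed effects (se):",
        ]
        se = np.sqrt(np.maximum(np.diag(self.cov_joint)[: m.n_fixed], 0.0))
        for name, b, s in zip(m.fixed_names, self.fe_params, se):
            lines.append(f"    {name:<22s} {b:+.5f} ({s:.5f})")
        return "\n".join(lines)

    def to_json(self) -> str:
        m = self.model
        return json.dumps(
            {
                "spec": {"basis": m.spec.basis, "penalty": m.spec.penalty,
                         "n_knots": m.spec.n_knots},
                "structure": {"name": m.structure.name,
                              "terms": [[c, sorted(comps)] for c, comps in m.structure.terms]},
                "knots": m.basis.knots.tolist(),
                "method": self.method,
                "fe_params": dict(zip(m.fixed_names, map(float, self.fe_params))),
                "blups": self.blups.tolist(),
                "variance": {"sigma2": self.sigma2, "tau2": self.tau2,
                             "subject": list(self.subject_var)},
                "llf": self.llf, "aic": self.aic, "bic": self.bic,
                "converged": self.converged,
            }
        )
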