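"""Weighted linear mixed model with family random effects.

The marginal model per family ``f`` is

    V_f = Z_f G Z_f' + sigma^2 * diag(1 / w_f)

where ``Z_f`` holds a family intercept (optionally also a family age
slope), ``G`` is diagonal, and ``w`` are per-observation weights that
scale residual precision.  Variance ratios ``gamma = diag(G) / sigma^2``
are profiled: for fixed ``gamma`` the GLS fixed effects and ``sigma^2``
are available in closed form, leaving a 1- or 2-dimensional (restricted)
likelihood optimisation.  All per-family quantities are computed through
low-rank (Woodbury) updates grouped with ``np.add.reduceat``, so a single
likelihood evaluation is a handful of vectorised passes over the data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm

from .exceptions import ConvergenceError, InputError

logger = logging.getLogger(__name__)

__all__ = ["DesignMatrices", "WlmmFit", "build_design", "fit", "pseudo_r2"]



@dataclass
class DesignMatrices:
    """Assembled fixed/random designs for one model fit."""

    X: np.ndarray
    xnames: list[str]
    y: np.ndarray
    family_codes: np.ndarray
    age_z: np.ndarray
    random_slope: bool
    n_families: int
    index: np.ndarray  # row labels of the source table, for traceability

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def drop_term(self, name: str) -> "DesignMatrices":
        """Design with one fixed-effect column removed (for nested fits)."""
        if name not in self.xnames:
            raise InputError(f"no fixed-effect column named {name!r}")
        keep = [i for i, nm in enumerate(self.xnames) if nm != name]
        return DesignMatrices(
            X=self.X[:, keep],
            xnames=[self.xnames[i] for i in keep],
            y=self.y,
            family_codes=self.family_codes,
            age_z=self.age_z,
            random_slope=self.random_slope,
            n_families=self.n_families,
            index=self.index,
        )


def build_design(df: pd.DataFrame, random_slope: bool = False) -> DesignMatrices:
    """Assemble X, y and the family grouping from a standardized table.

    Fixed effects: intercept, PGS, age, age^2, sex, genotyping-array
    dummies (reference = most frequent level), and five principal
    components.  Constant or aliased dummy columns are dropped with a
    warning; a rank-deficient X after dropping raises an error naming the
    collinear columns.
    """
    required = ["person", "family", "phenotype", "pgs", "age_z", "age2_z", "sex"] + [
        f"pc{i}" for i in range(1, 6)
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"missing model columns: {missing}")
    model_cols = required + (["array"] if "array" in df.columns else [])
    if df[model_cols].isna().any().any():
        bad = df[model_cols].isna().any()
        raise InputError(
            f"missing values in model columns: {list(bad.index[bad])}"
        )

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    cols["pgs"] = df["pgs"].to_numpy(float)
    cols["age_z"] = df["age_z"].to_numpy(float)
    cols["age2_z"] = df["age2_z"].to_numpy(float)
    cols["sex"] = df["sex"].to_numpy(float)
    if "array" in df.columns:
        arr = df["array"].astype("category")
        ref = arr.value_counts().idxmax()
        for level in arr.cat.categories:
            if level == ref:
                continue
            dummy = (arr == level).to_numpy(float)
            if dummy.std() == 0:
                logger.warning("array dummy %r is constant; dropped", level)
                continue
            cols[f"array[{level}]"] = dummy
    for i in range(1, 6):
        cols[f"pc{i}"] = df[f"pc{i}"].to_numpy(float)

    # drop non-intercept columns with zero variance (aliased)
    for nm in [n for n in list(cols) if n != "intercept"]:
        if np.std(cols[nm]) == 0:
            logger.warning("fixed-effect column %r is constant; dropped", nm)
            del cols[nm]

    xnames = list(cols)
    X = np.column_stack([cols[nm] for nm in xnames])
    if X.shape[0] >= X.shape[1]:  # collinearity is only meaningful with n >= p
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, _, piv = qr(X, mode="economic", pivoting=True)
            culprits = sorted(xnames[i] for i in piv[rank:])
            raise InputError(
                f"design matrix is rank deficient; collinear columns: {culprits}"
            )

    fam_codes, fam_levels = pd.factorize(df["family"].to_numpy())
    return DesignMatrices(
        X=X,
        xnames=xnames,
        y=df["phenotype"].to_numpy(float),
        family_codes=fam_codes,
        age_z=df["age_z"].to_numpy(float),
        random_slope=random_slope,
        n_families=len(fam_levels),
        index=df.index.to_numpy(),
    )


@dataclass
class WlmmFit:
    """One fitted weighted mixed model."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    family_var: float
    slope_var: float | None
    gamma: np.ndarray
    loglik: float
    method: str
    n_rows: int
    n_families: int
    sum_weights: float
    converged: bool
    boundary: bool
    pseudo_r2: float | None = None
    n_params_fixed: int = 0

    def __getitem__(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * norm.sf(np.abs(self.zvalues))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def to_record(self) -> dict:
        """JSON-serialisable run record."""
        rec = {
            "method": self.method,
            "loglik": self.loglik,
            "sigma2": self.sigma2,
            "family_var": self.family_var,
            "slope_var": self.slope_var,
            "n_rows": self.n_rows,
            "n_families": self.n_families,
            "sum_weights": self.sum_weights,
            "converged": self.converged,
            "boundary": self.boundary,
        }
        if self.pseudo_r2 is not None:
            rec["pseudo_r2"] = self.pseudo_r2
        return rec

    @property
    def total_variance(self) -> float:
        return self.sigma2 + self.family_var + (self.slope_var or 0.0)


def _family_blocks(codes: np.ndarray):
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) != 0])
    return order, starts


def _gls_pieces(X, y, d, U, starts, gamma):
    """GLS building blocks for V0 = diag(1/d) + U diag(gamma) U'.

    Returns (XtVX, XtVy, ytVy, logdetV0) where V is V0 (sigma^2 factored
    out).  Uses the Woodbury identity per family; ``starts`` are family
    block boundaries in the (family-sorted) rows.
    """
    sX = X * d[:, None]
    XtPX = X.T @ sX
    XtPy = sX.T @ y
    ytPy = float(d @ (y * y))
    logdet_diag = -float(np.log(d).sum())

    q = U.shape[1]
    sqrtg = np.sqrt(gamma)
    if np.all(gamma == 0):
        return XtPX, XtPy, ytPy, logdet_diag

    F = len(starts)
    S = np.empty((F, q, q))
    for a in range(q):
        for b in range(a, q):
            s_ab = np.add.reduceat(d * U[:, a] * U[:, b], starts)
            S[:, a, b] = s_ab
            S[:, b, a] = s_ab
    C = np.eye(q)[None, :, :] + S * (sqrtg[:, None] * sqrtg[None, :])
    Cinv = np.linalg.inv(C)
    sign, logdetC = np.linalg.slogdet(C)

    B = np.stack(
        [np.add.reduceat(sX * U[:, a][:, None], starts, axis=0) for a in range(q)],
        axis=2,
    )  # (F, p, q)
    B *= sqrtg
    c = np.stack(
        [np.add.reduceat(d * y * U[:, a], starts) for a in range(q)], axis=1
    ) * sqrtg  # (F, q)

    XtVX = XtPX - np.einsum("fpa,fab,fqb->pq", B, Cinv, B)
    XtVy = XtPy - np.einsum("fpa,fab,fb->p", B, Cinv, c)
    ytVy = ytPy - float(np.einsum("fa,fab,fb->", c, Cinv, c))
    return XtVX, XtVy, ytVy, logdet_diag + float(logdetC.sum())


_TINY = 1e-300


def fit(
    design: DesignMatrices,
    weights=None,
    method: str = "reml",
    fixed_ratios=None,
    drop_tol: float = 1e-12,
) -> WlmmFit:
    """Fit the weighted mixed model by profiled (restricted) ML.

    Parameters
    ----------
    weights
        Per-row nonnegative weights scaling residual precision (residual
        covariance ``sigma^2 / w``).  ``None`` means unit weights.  Rows
        with weight <= ``drop_tol`` are dropped, which is exactly
        equivalent to deleting them.
    method
        ``"reml"`` (default) or ``"ml"``.
    fixed_ratios
        Optional variance ratios ``gamma = variance_component / sigma^2``
        to hold fixed instead of optimising (e.g. ``(0.0,)`` forces an
        ordinary weighted LS fit).
    """
    method = method.lower()
    if method not in ("reml", "ml"):
        raise InputError(f"method must be 'reml' or 'ml', got {method!r}")
    n_all = design.n_rows
    w = np.ones(n_all) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n_all,):
        raise InputError("weights must align with the design rows")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise InputError("weights must be finite and nonnegative")
    sum_weights = float(w.sum())

    keep = w > drop_tol
    X, y, w_kept = design.X[keep], design.y[keep], w[keep]
    fam = design.family_codes[keep]
    age_z = design.age_z[keep]
    n, p = X.shape
    if n <= p:
        raise InputError(f"too few rows ({n}) for {p} fixed effects")
    # refactorize families present after dropping
    fam = pd.factorize(fam)[0]
    n_families = int(fam.max()) + 1
    if n_families < 2:
        logger.warning("fewer than 2 families; random effects weakly identified")

    order, starts = _family_blocks(fam)
    Xs, ys, ds = X[order], y[order], w_kept[order]
    if design.random_slope:
        U = np.column_stack([np.ones(n), age_z[order]])
    else:
        U = np.ones((n, 1))
    q = U.shape[1]

    dof = n - p if method == "reml" else n

    def crit(log_gamma: np.ndarray) -> float:
        gamma = np.exp(np.clip(log_gamma, -30.0, 20.0))
        XtVX, XtVy, ytVy, logdetV0 = _gls_pieces(Xs, ys, ds, U, starts, gamma)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = max(ytVy - float(XtVy @ beta), 0.0)
        val = dof * math.log(max(rss / dof, _TINY)) + logdetV0
        if method == "reml":
            sgn, ld = np.linalg.slogdet(XtVX)
            if sgn <= 0:
                return np.inf
            val += ld
        return val

    if fixed_ratios is not None:
        gamma = np.asarray(fixed_ratios, dtype=float)
        if gamma.shape != (q,):
            raise InputError(f"fixed_ratios must have {q} entries")
        converged = True
    elif q == 1:
        res = minimize_scalar(
            lambda lg: crit(np.array([lg])),
            bounds=(-20.0, 15.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        # a boundary fit (gamma -> 0) can beat an interior local optimum
        lg_best = res.x if crit(np.array([res.x])) <= crit(np.array([-30.0])) else -30.0
        gamma = np.exp(np.array([lg_best]))
        converged = bool(res.success)
    else:
        best = None
        for x0 in (np.zeros(q), np.full(q, -4.0)):
            res = minimize(
                crit, x0, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("variance-component optimisation failed", trace=best)
        converged = bool(best.success)
        gamma = np.exp(np.clip(best.x, -30.0, 20.0))

    XtVX, XtVy, ytVy, logdetV0 = _gls_pieces(Xs, ys, ds, U, starts, gamma)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - float(XtVy @ beta), 0.0)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    log_s2 = math.log(max(sigma2, _TINY))
    if method == "reml":
        sgn, ld_xtvx = np.linalg.slogdet(XtVX)
        loglik = -0.5 * (
            dof * (math.log(2 * math.pi) + 1.0 + log_s2) + logdetV0 + ld_xtvx
        )
    else:
        loglik = -0.5 * (n * (math.log(2 * math.pi) + 1.0 + log_s2) + logdetV0)

    boundary = bool(np.any(gamma < 1e-7)) or sigma2 < 1e-12
    if boundary:
        logger.info("variance component at boundary (gamma=%s, sigma2=%.3g)", gamma, sigma2)

    return WlmmFit(
        terms=list(design.xnames),
        beta=beta,
        se=se,
        sigma2=sigma2,
        family_var=float(gamma[0] * sigma2),
        slope_var=float(gamma[1] * sigma2) if q == 2 else None,
        gamma=gamma,
        loglik=loglik,
        method=method,
        n_rows=n,
        n_families=n_families,
        sum_weights=sum_weights,
        converged=converged,
        boundary=boundary,
        n_params_fixed=p,
    )


def pseudo_r2(fit_with_pgs: WlmmFit, fit_without_pgs: WlmmFit) -> float:
    """Proportional reduction in total (random + residual) variance.

    Both fits must be on identical rows and weights, differing only by the
    PGS column.  For standardized outcome and PGS with marginal effect
    ``beta`` this is approximately ``beta^2``.
    """
    if fit_with_pgs.n_rows != fit_without_pgs.n_rows or not math.isclose(
        fit_with_pgs.sum_weights, fit_without_pgs.sum_weights, rel_tol=1e-12
    ):
        raise InputError("fits are not on identical rows/weights")
    t0 = fit_without_pgs.total_variance
    t1 = fit_with_pgs.total_variance
    if t0 <= 0:
        raise InputError("reference model has zero total variance")
    return (t0 - t1) / t0
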