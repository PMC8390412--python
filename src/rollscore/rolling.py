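"""Per-focus-age driver: standardization, rolling weighted fits, bootstrap.

One weighted mixed model is fitted per integer focus age.  The kernel is
always computed on raw (unstandardized) ages over the full analysis
dataset, while the model's age covariates use standardized age — two
deliberately distinct representations.  Confidence intervals come from a
family-block bootstrap: whole families are resampled with replacement and
the focus-age model refitted per resample.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import wlmm
from .exceptions import ConvergenceError, InputError
from .kernel import KernelParams, compute_weights

logger = logging.getLogger(__name__)

__all__ = [
    "RollingResult",
    "standardize",
    "fit_pooled",
    "run_rolling",
    "bootstrap_ci",
    "results_to_frame",
]

#: rows with final kernel weight below this are dropped from a per-age fit
WEIGHT_FLOOR = 1e-8

#: columns standardized once over the full dataset before any analysis
CONTINUOUS_COLUMNS = ("phenotype", "pgs", "age", "pc1", "pc2", "pc3", "pc4", "pc5")


@dataclass(frozen=True)
class RollingResult:
    """PGS effect at one focus age with bootstrap uncertainty."""

    focus_age: float
    estimate: float
    model_se: float
    boot_se: float
    ci_low: float
    ci_high: float
    effective_n: float
    n_rows: int
    significant: bool
    n_boot: int
    n_boot_failed: int = 0
    failed: bool = False
    error: str | None = None


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Center and scale continuous model columns to unit SD, once, globally.

    Standardizes phenotype, PGS and the PCs in place (copy), and adds
    ``age_z`` / ``age2_z`` columns; ``age2_z`` is the square of
    standardized age.  The raw ``age`` column is kept for the kernel.
    Idempotent: already-standardized columns are unchanged.
    """
    out = data.copy()
    for col in CONTINUOUS_COLUMNS:
        if col not in out.columns:
            raise InputError(f"missing continuous column {col!r}")
        v = out[col].to_numpy(float)
        sd = v.std()
        if sd == 0 or not np.isfinite(sd):
            raise InputError(f"zero-variance column {col!r} cannot be standardized")
        z = (v - v.mean()) / sd
        if col == "age":
            out["age_z"] = z
        else:
            out[col] = z
    out["age2_z"] = out["age_z"] ** 2
    return out


def fit_pooled(
    data: pd.DataFrame, random_slope: bool = False, method: str = "reml"
) -> wlmm.WlmmFit:
    """Unweighted mixed-model fit on the total sample, with pseudo-R^2.

    The returned fit carries ``pseudo_r2``, the proportional reduction in
    total variance relative to the same model without the PGS column.
    """
    design = wlmm.build_design(data, random_slope=random_slope)
    fit_with = wlmm.fit(design, weights=None, method=method)
    fit_without = wlmm.fit(design.drop_term("pgs"), weights=None, method=method)
    fit_with.pseudo_r2 = wlmm.pseudo_r2(fit_with, fit_without)
    return fit_with


def _slice_design(base: wlmm.DesignMatrices, rows) -> wlmm.DesignMatrices:
    return wlmm.DesignMatrices(
        X=base.X[rows],
        xnames=base.xnames,
        y=base.y[rows],
        family_codes=base.family_codes[rows],
        age_z=base.age_z[rows],
        random_slope=base.random_slope,
        n_families=base.n_families,
        index=base.index[rows],
    )


def _fit_at_age_design(
    base: wlmm.DesignMatrices,
    raw_ages: np.ndarray,
    focus_age: float,
    shoulder: float,
    decay: float,
    method: str,
):
    """One weighted fit centered at ``focus_age`` on a prebuilt design."""
    params = KernelParams(center=float(focus_age), shoulder=shoulder, decay=decay)
    wv = compute_weights(raw_ages, params)
    eff_n = wv.effective_n  # sum of all weights, before any dropping
    keep = wv.final >= WEIGHT_FLOOR
    fit = wlmm.fit(_slice_design(base, keep), weights=wv.final[keep], method=method)
    return fit, eff_n, int(keep.sum())


def _fit_at_age(
    data: pd.DataFrame,
    focus_age: float,
    shoulder: float,
    decay: float,
    random_slope: bool,
    method: str,
):
    """One weighted fit centered at ``focus_age``; returns (fit, effective_n, n_rows)."""
    base = wlmm.build_design(data, random_slope=random_slope)
    return _fit_at_age_design(
        base, data["age"].to_numpy(float), focus_age, shoulder, decay, method
    )


def _family_row_groups(data: pd.DataFrame):
    codes = pd.factorize(data["family"].to_numpy())[0]
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) != 0])
    groups = np.split(order, starts[1:])
    return groups


def bootstrap_ci(
    data: pd.DataFrame,
    result: RollingResult,
    n_boot: int = 100,
    seed: int = 0,
    shoulder: float = 1.5,
    decay: float = 25.0,
    random_slope: bool = False,
    method: str = "reml",
) -> RollingResult:
    """Attach a family-block bootstrap SE and 95% CI to one per-age result.

    Each replicate resamples the observed number of complete families with
    replacement (all of a family's rows travel together; duplicated
    families get fresh ids), recomputes the kernel weights on the resampled
    ages, and refits the focus-age model.  The bootstrap SE is the SD of
    the resampled PGS effects; the CI is ``estimate +- 1.96 * boot SE``,
    significant when it excludes zero.  Replicate RNG streams derive
    deterministically from ``(seed, focus age, replicate)``, so results do
    not depend on execution order.
    """
    if "family" not in data.columns:
        raise InputError("family ids are required for the family bootstrap")
    prep = _prepare(data, random_slope)
    return _bootstrap_prepared(
        prep, result, n_boot=n_boot, seed=seed,
        shoulder=shoulder, decay=decay, method=method,
    )


def _prepare(data: pd.DataFrame, random_slope: bool) -> dict:
    """Design matrices and family row groups, built once per analysis run."""
    return {
        "design": wlmm.build_design(data, random_slope=random_slope),
        "raw_ages": data["age"].to_numpy(float),
        "groups": _family_row_groups(data),
    }


def _bootstrap_prepared(
    prep: dict,
    result: RollingResult,
    n_boot: int,
    seed: int,
    shoulder: float,
    decay: float,
    method: str,
) -> RollingResult:
    base, raw_ages, groups = prep["design"], prep["raw_ages"], prep["groups"]
    n_fam = len(groups)
    sizes = np.array([len(g) for g in groups])
    focus_key = int(round(result.focus_age))
    params = KernelParams(center=float(result.focus_age), shoulder=shoulder, decay=decay)
    pgs_idx = base.xnames.index("pgs")

    betas = []
    n_failed = 0
    for rep in range(n_boot):
        rng = np.random.default_rng([int(seed), focus_key, rep])
        pick = rng.integers(0, n_fam, n_fam)
        rows = np.concatenate([groups[k] for k in pick])
        newfam = np.repeat(np.arange(n_fam), sizes[pick])
        try:
            wv = compute_weights(raw_ages[rows], params)
            keep = wv.final >= WEIGHT_FLOOR
            sub = _slice_design(base, rows)
            sub = _slice_design(sub, keep)
            sub.family_codes = newfam[keep]
            fit = wlmm.fit(sub, weights=wv.final[keep], method=method)
            betas.append(fit.beta[pgs_idx])
        except Exception as exc:  # noqa: BLE001 - any failed refit is dropped
            n_failed += 1
            logger.debug("bootstrap replicate %d failed at age %s: %s",
                         rep, result.focus_age, exc)
    if n_boot > 0 and n_failed > 0.2 * n_boot:
        raise ConvergenceError(
            f"{n_failed}/{n_boot} bootstrap replicates failed at age "
            f"{result.focus_age}"
        )
    if len(betas) >= 2:
        boot_se = float(np.std(betas, ddof=1))
    else:
        boot_se = 0.0
    ci_low = result.estimate - 1.96 * boot_se
    ci_high = result.estimate + 1.96 * boot_se
    significant = bool(ci_low > 0 or ci_high < 0)
    return dataclasses.replace(
        result,
        boot_se=boot_se,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        n_boot=len(betas),
        n_boot_failed=n_failed,
    )


def _analyze_age(
    prep: dict,
    focus_age: int,
    shoulder: float,
    decay: float,
    n_boot: int,
    seed: int,
    method: str,
) -> RollingResult:
    try:
        fit, eff_n, n_rows = _fit_at_age_design(
            prep["design"], prep["raw_ages"], focus_age, shoulder, decay, method
        )
    except Exception as exc:  # noqa: BLE001 - recorded, run continues
        logger.warning("fit failed at focus age %s: %s", focus_age, exc)
        return RollingResult(
            focus_age=float(focus_age),
            estimate=np.nan,
            model_se=np.nan,
            boot_se=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            effective_n=np.nan,
            n_rows=0,
            significant=False,
            n_boot=0,
            failed=True,
            error=str(exc),
        )
    res = RollingResult(
        focus_age=float(focus_age),
        estimate=fit["pgs"],
        model_se=fit.se_of("pgs"),
        boot_se=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        effective_n=eff_n,
        n_rows=n_rows,
        significant=False,
        n_boot=0,
    )
    if n_boot > 0:
        try:
            res = _bootstrap_prepared(
                prep, res, n_boot=n_boot, seed=seed,
                shoulder=shoulder, decay=decay, method=method,
            )
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            logger.warning("bootstrap failed at focus age %s: %s", focus_age, exc)
            res = dataclasses.replace(res, failed=True, error=str(exc))
    return res


def run_rolling(
    data: pd.DataFrame,
    age_min: int,
    age_max: int,
    shoulder: float = 1.5,
    decay: float = 25.0,
    n_boot: int = 100,
    seed: int = 0,
    random_slope: bool = False,
    method: str = "reml",
    n_jobs: int = 1,
) -> list[RollingResult]:
    """One weighted mixed-model analysis per integer focus age.

    ``data`` must already be standardized (see :func:`standardize`).  The
    grid covers every integer in ``[age_min, age_max]`` even where a
    specific age has no raw rows — the kernel borrows information from
    adjacent ages.  A focus age whose fit fails is recorded as failed and
    the run continues.  Per-age analyses are independent; results are
    invariant to execution order.
    """
    if age_min > age_max:
        raise InputError(f"empty focus-age range [{age_min}, {age_max}]")
    for col in ("age", "age_z", "age2_z"):
        if col not in data.columns:
            raise InputError("data must be standardized first (missing age_z/age2_z)")
    ages = list(range(int(age_min), int(age_max) + 1))
    obs_min, obs_max = data["age"].min(), data["age"].max()
    if age_min < obs_min - 1 or age_max > obs_max + 1:
        logger.warning(
            "focus-age range [%s, %s] extends beyond observed ages [%.1f, %.1f]",
            age_min, age_max, obs_min, obs_max,
        )

    prep = _prepare(data, random_slope)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_analyze_age)(prep, a, shoulder, decay, n_boot, seed, method)
            for a in ages
        )
    else:
        results = [
            _analyze_age(prep, a, shoulder, decay, n_boot, seed, method)
            for a in ages
        ]
    n_failed = sum(r.failed for r in results)
    if n_failed:
        logger.warning(
            "%d of %d focus-age fits failed: ages %s",
            n_failed, len(results), [r.focus_age for r in results if r.failed],
        )
    return results


def results_to_frame(results: list[RollingResult]) -> pd.DataFrame:
    """Rolling results as a table, one row per focus age."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
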