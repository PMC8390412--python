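"""Synthetic family-structured longitudinal data with known ground truth.

Families share a polygenic-score component (so PGS values are correlated
within family) and a random intercept (optionally an age slope); each
person contributes repeated measures at different ages.  The phenotype is

    beta(age) * PGS + covariate effects + family effects + noise

with every generating value returned alongside the data, so recovery can
be tested end-to-end.  Ordinal item responses per wave are drawn from a
GPCM given the per-measure latent values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .gpcm import ItemResponseMatrix

__all__ = ["SimConfig", "beta_from_spec", "simulate_measures", "simulate_items"]


def beta_from_spec(spec) -> Callable[[np.ndarray], np.ndarray]:
    """Turn a config value into an age-varying effect function.

    Accepts a number (constant effect), a callable, or a mapping
    ``{"type": "constant", "value": v}`` /
    ``{"type": "step", "before": v1, "after": v2, "change_age": a}``.
    """
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        v = float(spec)
        return lambda age: np.full_like(np.asarray(age, float), v)
    if isinstance(spec, dict):
        kind = spec.get("type", "constant")
        if kind == "constant":
            return beta_from_spec(float(spec["value"]))
        if kind == "step":
            before, after = float(spec["before"]), float(spec["after"])
            change = float(spec["change_age"])
            return lambda age: np.where(np.asarray(age, float) <= change, before, after)
        raise InputError(f"unknown beta_age spec type {kind!r}")
    raise InputError(f"cannot interpret beta_age spec {spec!r}")


@dataclass
class SimConfig:
    """Generating parameters for one synthetic dataset."""

    n_families: int = 400
    family_size: tuple[int, int] = (2, 4)  # inclusive range
    measures_per_person: tuple[int, int] = (1, 3)  # inclusive range
    age_range: tuple[float, float] = (12.0, 70.0)
    age_mode: str = "uniform"  # or "bimodal"
    pgs_family_corr: float = 0.5
    beta_age: object = 0.05  # number, callable, or spec dict
    sex_effect: float = 0.0
    pc_effects: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    n_arrays: int = 2
    array_effect: float = 0.0
    family_var: float = 0.2
    slope_var: float = 0.0
    resid_var: float = 0.8
    # item-response structure
    n_waves: int = 1
    n_items: int = 15
    n_categories: int = 3
    disc_range: tuple[float, float] = (0.8, 2.0)
    step_range: tuple[float, float] = (-1.5, 1.5)
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_families < 1:
            raise InputError("n_families must be >= 1")
        if self.family_size[0] < 1 or self.family_size[0] > self.family_size[1]:
            raise InputError(f"invalid family_size range {self.family_size}")
        if (
            self.measures_per_person[0] < 1
            or self.measures_per_person[0] > self.measures_per_person[1]
        ):
            raise InputError(f"invalid measures_per_person range {self.measures_per_person}")
        if self.age_range[0] >= self.age_range[1]:
            raise InputError(f"invalid age_range {self.age_range}")
        if not 0.0 <= self.pgs_family_corr <= 1.0:
            raise InputError("pgs_family_corr must lie in [0, 1]")
        for nm in ("family_var", "slope_var", "resid_var", "missing_rate"):
            if getattr(self, nm) < 0:
                raise InputError(f"{nm} must be nonnegative")
        if self.missing_rate >= 1:
            raise InputError("missing_rate must be < 1")
        if len(self.pc_effects) != 5:
            raise InputError("pc_effects must have 5 entries")
        if self.n_arrays < 1:
            raise InputError("n_arrays must be >= 1")
        if self.n_categories < 2:
            raise InputError("items need at least 2 categories")
        if self.age_mode not in ("uniform", "bimodal"):
            raise InputError(f"unknown age_mode {self.age_mode!r}")


def _draw_ages(cfg: SimConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.age_range
    if cfg.age_mode == "uniform":
        return rng.uniform(lo, hi, size)
    # bimodal preset: a young and an adult cluster, clipped into range
    span = hi - lo
    centers = np.where(rng.random(size) < 0.5, lo + 0.15 * span, lo + 0.65 * span)
    return np.clip(rng.normal(centers, 0.12 * span), lo, hi)


def _array_level_effects(cfg: SimConfig) -> np.ndarray:
    k = cfg.n_arrays
    if k == 1:
        return np.zeros(1)
    idx = np.arange(k) - (k - 1) / 2
    return cfg.array_effect * idx / idx.std()


def simulate_measures(
    config: SimConfig, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Draw one long-format measures table plus its ground-truth record.

    The returned truth dict holds the generating effect values, per-person
    latent phenotype values (for item simulation), and the analytic
    phenotype variance implied by the configuration.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    beta = beta_from_spec(config.beta_age)

    fam_sizes = rng.integers(
        config.family_size[0], config.family_size[1] + 1, config.n_families
    )
    n_persons = int(fam_sizes.sum())
    family = np.repeat(np.arange(config.n_families), fam_sizes)
    person = np.arange(n_persons)

    # PGS: shared family component + individual component, unit variance
    rho = config.pgs_family_corr
    z_fam = rng.standard_normal(config.n_families)
    pgs = np.sqrt(rho) * z_fam[family] + np.sqrt(1 - rho) * rng.standard_normal(n_persons)

    sex = rng.integers(0, 2, n_persons)
    pcs = rng.standard_normal((n_persons, 5))
    array_idx = rng.integers(0, config.n_arrays, n_persons)
    arr_eff = _array_level_effects(config)

    b0_fam = rng.normal(0.0, np.sqrt(config.family_var), config.n_families)
    b1_fam = rng.normal(0.0, np.sqrt(config.slope_var), config.n_families)

    n_meas = rng.integers(
        config.measures_per_person[0], config.measures_per_person[1] + 1, n_persons
    )
    midx = np.repeat(np.arange(n_persons), n_meas)
    total = len(midx)
    # k-th measure of each person gets wave label "wk", so (person, wave)
    # is unique as in survey data
    within = np.concatenate([np.arange(k) for k in n_meas])
    ages = _draw_ages(config, total, rng)

    lo, hi = config.age_range
    # centered/scaled age multiplying the family slope, unit variance under
    # the uniform age distribution
    age_c = (ages - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12.0))

    pc_eff = np.asarray(config.pc_effects, float)
    genetic = beta(ages) * pgs[midx]
    signal = (
        genetic
        + config.sex_effect * sex[midx]
        + pcs[midx] @ pc_eff
        + arr_eff[array_idx[midx]]
        + b0_fam[family[midx]]
        + b1_fam[family[midx]] * age_c
    )
    phenotype = signal + rng.normal(0.0, np.sqrt(config.resid_var), total)

    df = pd.DataFrame(
        {
            "measure": np.arange(total),
            "person": midx,
            "family": family[midx],
            "age": ages,
            "phenotype": phenotype,
            "pgs": pgs[midx],
            "sex": sex[midx],
            "array": np.array([f"array{i + 1}" for i in array_idx[midx]]),
            "wave": np.array([f"w{k + 1}" for k in within]),
        }
    )
    for i in range(5):
        df[f"pc{i + 1}"] = pcs[midx, i]

    # analytic phenotype variance: independent additive components
    grid = np.linspace(lo, hi, 2001)
    e_beta2 = float(np.mean(beta(grid) ** 2))
    analytic_var = (
        e_beta2
        + config.sex_effect**2 * 0.25
        + float(pc_eff @ pc_eff)
        + float(np.mean(arr_eff**2) - np.mean(arr_eff) ** 2)
        + config.family_var
        + config.slope_var
        + config.resid_var
    )

    truth = {
        "seed": seed,
        "beta_on_grid": {int(a): float(beta(np.array([a]))[0]) for a in range(int(lo), int(hi) + 1)},
        "analytic_phenotype_variance": analytic_var,
        "family_var": config.family_var,
        "slope_var": config.slope_var,
        "resid_var": config.resid_var,
        "n_persons": n_persons,
        "n_measures": total,
        "latent_signal": signal,  # per-measure, for item simulation
    }
    return df, truth


def simulate_items(
    config: SimConfig, thetas: np.ndarray, seed: int = 0
) -> tuple[list[ItemResponseMatrix], dict]:
    """Draw per-wave ordinal item responses from a GPCM given ``thetas``.

    ``thetas`` holds one latent value per person; persons are split evenly
    across waves (each person responds in one wave).  Missing entries are
    injected completely at random at ``config.missing_rate``.  Returns the
    per-wave matrices and the generating item parameters.
    """
    config.validate()
    thetas = np.asarray(thetas, float)
    if thetas.ndim != 1 or thetas.size == 0:
        raise InputError("thetas must be a non-empty 1-D array")
    rng = np.random.default_rng(seed)
    n = thetas.size
    wave_of = rng.integers(0, config.n_waves, n) if config.n_waves > 1 else np.zeros(n, int)

    K = config.n_categories
    tables: list[ItemResponseMatrix] = []
    truth: dict = {"waves": []}
    for w in range(config.n_waves):
        sel = np.flatnonzero(wave_of == w)
        th = thetas[sel]
        a = rng.uniform(*config.disc_range, config.n_items)
        steps = np.sort(
            rng.uniform(*config.step_range, (config.n_items, K - 1)), axis=1
        )
        # intercepts d_k = -a * cumsum(b), d_0 = 0
        d = -a[:, None] * np.cumsum(steps, axis=1)
        resp = np.empty((len(sel), config.n_items), dtype=int)
        kvec = np.arange(K)
        for j in range(config.n_items):
            eta = np.outer(th, kvec * a[j])
            eta[:, 1:] += d[j]
            eta -= eta.max(axis=1, keepdims=True)
            p = np.exp(eta)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(len(sel))
            resp[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        if config.missing_rate > 0:
            mask = rng.random(resp.shape) < config.missing_rate
            resp[mask] = -1
        tables.append(
            ItemResponseMatrix(
                responses=resp,
                n_categories=np.full(config.n_items, K),
                person_ids=sel,
                wave=f"wave{w + 1}",
                item_names=[f"item{j + 1}" for j in range(config.n_items)],
            )
        )
        truth["waves"].append(
            {"wave": f"wave{w + 1}", "discriminations": a, "steps": steps,
             "persons": sel, "thetas": th}
        )
    return tables, truth
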