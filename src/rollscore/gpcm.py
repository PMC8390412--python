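"""Generalized Partial Credit Model: per-wave fitting and EAP scoring.

Responses to ordered polytomous items (categories ``0..K-1``) are modelled
with per-item discriminations and step parameters under a standard-normal
latent trait.  Estimation is marginal maximum likelihood via EM with fixed
quadrature; scoring is expected-a-posteriori (EAP).  Missing items simply
contribute nothing to a person's likelihood.

The model for item ``j`` with slope ``a_j`` and intercepts ``d_jk`` is::

    P(X_j = k | theta)  propto  exp(k * a_j * theta + d_jk),   d_j0 = 0

which is the usual slope/intercept form; step parameters ``b_jk`` are
recovered as ``(d_j,k-1 - d_jk) / a_j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .exceptions import ConvergenceError, DegenerateInputError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ItemResponseMatrix",
    "GpcmModel",
    "TraitScores",
    "filter_missing",
    "fit_gpcm",
    "score_eap",
    "score_waves",
]

MISSING = -1


@dataclass
class ItemResponseMatrix:
    """Persons x items ordinal responses for one wave; ``-1`` marks missing."""

    responses: np.ndarray
    n_categories: np.ndarray
    person_ids: np.ndarray
    wave: str = "wave1"
    item_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        if self.responses.ndim != 2:
            raise InputError("responses must be a 2-D persons x items array")
        self.n_categories = np.asarray(self.n_categories, dtype=int)
        if self.n_categories.shape != (self.responses.shape[1],):
            raise InputError("n_categories must have one entry per item")
        if np.any(self.n_categories < 2):
            raise InputError("every item needs at least 2 categories")
        self.person_ids = np.asarray(self.person_ids)
        if self.person_ids.shape != (self.responses.shape[0],):
            raise InputError("person_ids must have one entry per person")
        bad = (self.responses < MISSING) | (self.responses >= self.n_categories)
        if np.any(bad):
            raise InputError(
                "responses outside the items' category ranges at "
                f"{np.argwhere(bad)[:5].tolist()} ..."
            )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        item_cols: list[str],
        person_col: str = "person",
        wave: str = "wave1",
        n_categories=None,
    ) -> "ItemResponseMatrix":
        """Build from a wide table; blank/NaN cells become missing."""
        missing_cols = [c for c in [person_col, *item_cols] if c not in df.columns]
        if missing_cols:
            raise InputError(f"missing columns in item table: {missing_cols}")
        raw = df[item_cols].to_numpy(dtype=float)
        resp = np.where(np.isnan(raw), MISSING, raw).astype(int)
        if n_categories is None:
            n_categories = np.where(
                resp.max(axis=0) >= 1, resp.max(axis=0) + 1, 2
            )
        return cls(
            responses=resp,
            n_categories=np.asarray(n_categories, dtype=int),
            person_ids=df[person_col].to_numpy(),
            wave=wave,
            item_names=list(item_cols),
        )

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def missing_per_person(self) -> np.ndarray:
        return (self.responses == MISSING).sum(axis=1)


def filter_missing(raw: ItemResponseMatrix, max_missing: int = 2) -> ItemResponseMatrix:
    """Retain persons with at most ``max_missing`` missing items."""
    keep = raw.missing_per_person() <= max_missing
    n_drop = int((~keep).sum())
    logger.info(
        "filter_missing(wave=%s): retained %d, dropped %d persons "
        "(> %d missing items)",
        raw.wave,
        int(keep.sum()),
        n_drop,
        max_missing,
    )
    if keep.all():
        return raw
    return ItemResponseMatrix(
        responses=raw.responses[keep],
        n_categories=raw.n_categories,
        person_ids=raw.person_ids[keep],
        wave=raw.wave,
        item_names=raw.item_names,
    )


@dataclass
class GpcmModel:
    """Fitted GPCM for one wave's item set."""

    discriminations: np.ndarray
    intercepts: list[np.ndarray]  # per item, length K_j - 1 (d_j1..d_j,K-1)
    n_categories: np.ndarray
    quad_points: np.ndarray
    quad_logprior: np.ndarray
    loglik: float
    trace: np.ndarray
    converged: bool
    n_iter: int
    wave: str = "wave1"
    item_names: list[str] | None = None
    dropped_items: list[int] = field(default_factory=list)

    @property
    def step_parameters(self) -> list[np.ndarray]:
        """Per-item step parameters b_jk = (d_{k-1} - d_k) / a."""
        out = []
        for a, d in zip(self.discriminations, self.intercepts):
            dfull = np.concatenate([[0.0], d])
            out.append((dfull[:-1] - dfull[1:]) / a)
        return out

    def category_logprobs(self, j: int) -> np.ndarray:
        """Log P(X_j = k | theta) on the quadrature grid, shape (K_j, Q)."""
        return _cat_logprobs(
            self.discriminations[j], self.intercepts[j], self.quad_points
        )


@dataclass
class TraitScores:
    """EAP latent scores keyed by (person, wave)."""

    table: pd.DataFrame  # columns: person, wave, score, posterior_sd

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @classmethod
    def concat(cls, parts: list["TraitScores"]) -> "TraitScores":
        return cls(pd.concat([p.table for p in parts], ignore_index=True))


def _cat_logprobs(a: float, d: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(K, Q) log category probabilities for one item."""
    k = np.arange(len(d) + 1)
    eta = np.outer(k * a, theta)  # (K, Q)
    eta[1:] += d[:, None]
    return eta - logsumexp(eta, axis=0, keepdims=True)


def _person_loglik_grid(
    resp: np.ndarray, disc: np.ndarray, intercepts: list[np.ndarray], theta: np.ndarray
) -> np.ndarray:
    """(n, Q) log-likelihood of each person's observed responses per node."""
    n, J = resp.shape
    ll = np.zeros((n, len(theta)))
    for j in range(J):
        logp = _cat_logprobs(disc[j], intercepts[j], theta)  # (K, Q)
        obs = resp[:, j] != MISSING
        ll[obs] += logp[resp[obs, j]]
    return ll


def _neg_expected_item_ll(x: np.ndarray, r: np.ndarray, theta: np.ndarray):
    """Negative expected complete-data log-lik for one item, with gradient.

    ``r`` is the (Q, K) table of expected counts from the E-step,
    ``x = [a, d_1..d_{K-1}]``.
    """
    a, d = x[0], x[1:]
    K = len(d) + 1
    k = np.arange(K)
    eta = np.outer(theta, k * a)  # (Q, K)
    eta[:, 1:] += d
    lse = logsumexp(eta, axis=1, keepdims=True)
    logp = eta - lse
    f = -float((r * logp).sum())
    p = np.exp(logp)  # (Q, K)
    Rq = r.sum(axis=1)  # (Q,)
    # d/da: sum_qk r_qk * k * theta_q  -  sum_q R_q * theta_q * E_q[k]
    g_a = -(float((r * (theta[:, None] * k)).sum()) - float((Rq * theta * (p @ k)).sum()))
    # d/dd_m: sum_q r_qm - sum_q R_q p_qm
    g_d = -(r[:, 1:].sum(axis=0) - Rq @ p[:, 1:])
    return f, np.concatenate([[g_a], g_d])


def fit_gpcm(
    data: ItemResponseMatrix,
    n_quadrature: int = 61,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GpcmModel:
    """Marginal ML fit by EM over a standard-normal latent trait.

    Items with a single observed category are dropped with a warning; a fit
    that has not reached ``tol`` (absolute change in marginal log-likelihood)
    by ``max_iter`` raises :class:`ConvergenceError` carrying the trace.
    """
    resp = data.responses
    if resp.shape[1] < 2:
        raise InputError("need at least 2 items to fit a GPCM")

    keep_items, dropped = [], []
    for j in range(resp.shape[1]):
        obs = resp[:, j][resp[:, j] != MISSING]
        if obs.size and np.unique(obs).size >= 2:
            keep_items.append(j)
        else:
            dropped.append(j)
            logger.warning(
                "item %d has a single observed category; dropped from the fit", j
            )
    if len(keep_items) < 2:
        raise DegenerateInputError(
            "fewer than 2 items with >= 2 observed categories remain "
            f"(dropped items: {dropped})"
        )
    resp = resp[:, keep_items]
    ncat = data.n_categories[keep_items]
    names = [data.item_names[j] for j in keep_items] if data.item_names else None

    theta = np.linspace(-6.0, 6.0, n_quadrature)
    logprior = -0.5 * theta**2
    logprior -= logsumexp(logprior)

    J = resp.shape[1]
    disc = np.ones(J)
    intercepts = []
    for j in range(J):
        obs = resp[:, j][resp[:, j] != MISSING]
        counts = np.bincount(obs, minlength=ncat[j]) + 0.5
        intercepts.append(np.log(counts[1:] / counts[0]))

    trace = []
    prev_ll = -np.inf
    converged = False
    for it in range(max_iter):
        # E-step
        ll_grid = _person_loglik_grid(resp, disc, intercepts, theta)
        joint = ll_grid + logprior
        person_ll = logsumexp(joint, axis=1)
        ll = float(person_ll.sum())
        trace.append(ll)
        post = np.exp(joint - person_ll[:, None])  # (n, Q)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        # M-step: per-item maximization of the expected complete-data ll
        for j in range(J):
            K = ncat[j]
            r = np.zeros((n_quadrature, K))
            col = resp[:, j]
            for k in range(K):
                sel = col == k
                if sel.any():
                    r[:, k] = post[sel].sum(axis=0)
            x0 = np.concatenate([[disc[j]], intercepts[j]])
            res = minimize(
                _neg_expected_item_ll,
                x0,
                args=(r, theta),
                jac=True,
                method="L-BFGS-B",
            )
            disc[j] = res.x[0]
            intercepts[j] = res.x[1:]

    if not converged:
        raise ConvergenceError(
            f"GPCM EM did not converge in {max_iter} iterations "
            f"(last change {trace[-1] - trace[-2]:.3g})",
            trace=np.asarray(trace),
        )

    # anchor the latent direction: flipping theta maps (a, d) -> (-a, d)
    if disc[0] < 0:
        disc = -disc

    return GpcmModel(
        discriminations=disc,
        intercepts=intercepts,
        n_categories=ncat,
        quad_points=theta,
        quad_logprior=logprior,
        loglik=trace[-1],
        trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
        wave=data.wave,
        item_names=names,
        dropped_items=dropped,
    )


def score_eap(model: GpcmModel, data: ItemResponseMatrix) -> TraitScores:
    """EAP score (posterior mean and SD) per person under the fitted model.

    Persons with missing items are scored on their observed items only; a
    person with no observed item among the model's items is an error.
    """
    cols = (
        [data.item_names.index(nm) for nm in model.item_names]
        if model.item_names and data.item_names
        else [j for j in range(data.n_items) if j not in model.dropped_items]
    )
    if len(cols) != len(model.discriminations):
        raise InputError("item set of data does not match the fitted model")
    resp = data.responses[:, cols]
    n_obs = (resp != MISSING).sum(axis=1)
    if np.any(n_obs == 0):
        bad = data.person_ids[n_obs == 0]
        raise InputError(
            f"persons with zero observed items cannot be scored: {bad[:5].tolist()}"
        )
    ll_grid = _person_loglik_grid(
        resp, model.discriminations, model.intercepts, model.quad_points
    )
    joint = ll_grid + model.quad_logprior
    post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    mean = post @ model.quad_points
    second = post @ model.quad_points**2
    sd = np.sqrt(np.maximum(second - mean**2, 0.0))
    return TraitScores(
        pd.DataFrame(
            {
                "person": data.person_ids,
                "wave": data.wave,
                "score": mean,
                "posterior_sd": sd,
            }
        )
    )


def score_waves(
    tables: list[ItemResponseMatrix],
    max_missing: int = 2,
    n_quadrature: int = 61,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> TraitScores:
    """Fit and score each wave independently; stack results by (person, wave).

    Fitting one model per wave makes scores relative to that wave's
    participants, removing wave-level shifts in endorsement.
    """
    if not tables:
        raise InputError("need at least one wave of item responses")
    parts = []
    for tab in tables:
        kept = filter_missing(tab, max_missing=max_missing)
        model = fit_gpcm(kept, n_quadrature=n_quadrature, tol=tol, max_iter=max_iter)
        parts.append(score_eap(model, kept))
    return TraitScores.concat(parts)
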