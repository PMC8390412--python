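"""Three-step construction of age weights for a focus-age analysis.

The weight attached to an observation depends on the distance between its
age and the focus age (the *center*):

1. a raw shoulder kernel ``w1 = 1 - |c - x|**s``,
2. min-max scaling of ``w1`` onto [0, 1],
3. a decay exponent applied elementwise, ``w = w2**decay``.

Observations at the center always receive weight exactly 1; the
observation farthest from the center receives weight exactly 0.  The
min-max step makes the weights relative to the observed age vector, so
the same center can yield different weights on different datasets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "KernelParams",
    "WeightVector",
    "stage1_raw",
    "stage2_minmax",
    "stage3_decay",
    "compute_weights",
]


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the age-weight kernel.

    Parameters
    ----------
    center
        Focus age in years; weights peak (at exactly 1) here.
    shoulder
        Positive exponent of the raw kernel, controlling the flatness of
        the peak.  Default 1.5.
    decay
        Positive exponent applied to the min-max scaled weights,
        controlling how fast weights fall toward zero.  Default 25.
    """

    center: float
    shoulder: float = 1.5
    decay: float = 25.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.center):
            raise InputError(f"kernel center must be finite, got {self.center!r}")
        if not (self.shoulder > 0 and math.isfinite(self.shoulder)):
            raise InputError(f"shoulder must be a positive real, got {self.shoulder!r}")
        if not (self.decay > 0 and math.isfinite(self.decay)):
            raise InputError(f"decay must be a positive real, got {self.decay!r}")


@dataclass(frozen=True)
class WeightVector:
    """All three stages of the weight construction, aligned to ``ages``."""

    ages: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    final: np.ndarray
    params: KernelParams
    uniform_fallback: bool = field(default=False)

    @property
    def effective_n(self) -> float:
        """Sum of final weights (the weighted analogue of sample size)."""
        return float(self.final.sum())

    def to_frame(self) -> pd.DataFrame:
        """Per-observation diagnostic table with all three weight stages."""
        return pd.DataFrame(
            {"age": self.ages, "w1": self.w1, "w2": self.w2, "weight": self.final}
        )


def _as_age_array(ages) -> np.ndarray:
    arr = np.asarray(ages, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise InputError("age vector is empty")
    if not np.all(np.isfinite(arr)):
        raise InputError("age vector contains non-finite values")
    return arr


def stage1_raw(ages, params: KernelParams) -> np.ndarray:
    """Raw shoulder kernel ``1 - |center - age|**shoulder``.

    The value at an age equal to the center is exactly 1; values far from
    the center may be (very) negative.
    """
    x = _as_age_array(ages)
    return 1.0 - np.abs(params.center - x) ** params.shoulder


def stage2_minmax(w1) -> np.ndarray:
    """Min-max scale a stage-1 vector onto [0, 1].

    Raises
    ------
    DegenerateInputError
        If all entries are equal (``max == min``), which happens when all
        observations are equidistant from the center — e.g. a single-age
        dataset.  Callers wanting uniform weight 1 in that case should use
        :func:`compute_weights`, which applies the fallback.
    """
    arr = np.asarray(w1, dtype=float)
    if arr.size == 0:
        raise InputError("stage-1 weight vector is empty")
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        raise DegenerateInputError(
            "min-max scaling is undefined: all stage-1 weights are equal "
            "(all observations are equidistant from the center; for a "
            "single-age dataset assign uniform weight 1 instead)"
        )
    return (arr - lo) / (hi - lo)


def stage3_decay(w2, decay: float) -> np.ndarray:
    """Apply the decay exponent elementwise: ``w2**decay``.

    Fixed points 0 and 1 are preserved; the map is strictly increasing on
    (0, 1), so ordering of weights is unchanged.
    """
    if not (decay > 0 and math.isfinite(decay)):
        raise InputError(f"decay must be a positive real, got {decay!r}")
    arr = np.asarray(w2, dtype=float)
    if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
        raise InputError("stage-2 weights must lie in [0, 1]")
    return np.clip(arr, 0.0, 1.0) ** decay


def compute_weights(ages, params: KernelParams) -> WeightVector:
    """Chain the three weight stages for one focus age.

    Observations whose age equals the center get final weight exactly 1;
    the observation most distant from the center gets exactly 0.  When all
    stage-1 values coincide (single-age or perfectly equidistant data) a
    uniform weight of 1 is assigned and a warning logged.
    """
    x = _as_age_array(ages)
    w1 = stage1_raw(x, params)
    try:
        w2 = stage2_minmax(w1)
        fallback = False
    except DegenerateInputError:
        logger.warning(
            "all observations equidistant from center %.3g "
            "(single-age dataset?); assigning uniform weight 1",
            params.center,
        )
        w2 = np.ones_like(w1)
        fallback = True
    final = stage3_decay(w2, params.decay)
    return WeightVector(
        ages=x, w1=w1, w2=w2, final=final, params=params, uniform_fallback=fallback
    )
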