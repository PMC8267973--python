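"""Closed-form logistic growth curve for carotid intima-media thickness (IMT).

The model treats a patient's IMT trajectory x(t) over chronological age t
(years, t = 0 at birth) as the solution of the logistic ODE

    dx/dt = a * x * (1 - x / c),    x(0) = x0,

whose closed form is

    x(t) = c * x0 * e^{a t} / (c + x0 * (e^{a t} - 1)).

``x0`` (mm) is a model abstraction of IMT at birth, ``c`` (mm) the carrying
capacity — the terminal IMT toward which the plaque converges — and ``a``
(1/year) the growth-rate coefficient.  The curve's steepest point sits at the
inflection age t* = ln((c - x0)/x0) / a, where IMT equals c/2 and the slope
peaks at a*c/4; those three analytic statistics drive the treatment-timing
analysis built on top of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import expit

__all__ = [
    "LogisticParams",
    "InflectionSummary",
    "imt_at_age",
    "growth_rate",
    "inflection",
    "mean_slope",
    "slope_profile",
    "round_age",
]

ArrayLike = Union[float, np.ndarray]


def round_age(t: float) -> int:
    """Round an age in years to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(t) + 0.5), t))


def round_sig(x: float, n_digits: int = 4) -> float:
    """Round to ``n_digits`` significant figures, halves away from zero.

    Decimal-based so that e.g. 0.0089145 rounds up to 0.008915 rather than
    falling to the binary-float representation's whim.
    """
    from decimal import ROUND_HALF_UP, Decimal

    if x == 0 or not math.isfinite(x):
        return float(x)
    shift = n_digits - 1 - math.floor(math.log10(abs(x)))
    d = Decimal(repr(x)).scaleb(shift).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(d.scaleb(-shift))


@dataclass(frozen=True)
class LogisticParams:
    """The (x0, c, a) triple defining one logistic IMT growth curve.

    Attributes
    ----------
    x0 : float
        IMT at age 0 (mm); must satisfy 0 < x0 < c.
    c : float
        Carrying capacity, the asymptotic terminal IMT (mm).
    a : float
        Growth-rate coefficient (1/year).
    """

    x0: float
    c: float
    a: float

    def __post_init__(self) -> None:
        for name in ("x0", "c", "a"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not self.x0 < self.c:
            raise ValueError(
                f"growth regime requires x0 < c, got x0={self.x0}, c={self.c}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x0, self.c, self.a)


@dataclass(frozen=True)
class InflectionSummary:
    """Inflection-point statistics of one logistic curve.

    ``t_star`` is the age of steepest growth (years), ``x_star`` the IMT
    there (always c/2, mm), ``max_slope`` the peak growth rate (always
    a*c/4, mm/year).  ``pre_observation`` flags curves whose inflection
    falls at or before age 0 (x0 >= c/2), i.e. the steepest point precedes
    any observable age.
    """

    t_star: float
    x_star: float
    max_slope: float
    pre_observation: bool

    @property
    def rounded_age(self) -> int:
        return round_age(self.t_star)


def _check_t(t: ArrayLike) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("age t must be finite")
    return arr


def imt_at_age(params: LogisticParams, t: ArrayLike) -> ArrayLike:
    """IMT (mm) at age ``t`` (years) on the logistic curve.

    Evaluated as c * expit(a*t - ln((c - x0)/x0)), algebraically identical to
    the closed form above but immune to overflow for any real ``t``.
    Accepts scalars or arrays; strictly increasing in t, bounded in (0, c).
    """
    arr = _check_t(t)
    p = params
    # ln r with r = (c - x0)/x0; expit keeps e^{a t} out of the arithmetic
    log_r = math.log((p.c - p.x0) / p.x0)
    out = p.c * expit(p.a * arr - log_r)
    return out if isinstance(out, np.ndarray) and np.ndim(t) else float(out)


def growth_rate(params: LogisticParams, t: ArrayLike) -> ArrayLike:
    """Instantaneous IMT growth rate dx/dt (mm/year) at age ``t``.

    Equals a * x(t) * (1 - x(t)/c), the analytic derivative of
    :func:`imt_at_age`; strictly positive for all finite ages.
    """
    x = imt_at_age(params, t)
    return params.a * x * (1.0 - x / params.c)


def inflection(params: LogisticParams) -> InflectionSummary:
    """Analytic inflection-point summary of the curve.

    t* = ln((c - x0)/x0) / a; x(t*) = c/2; slope there = a*c/4, the curve's
    maximum.  t* <= 0 (possible when x0 >= c/2) is reported with the
    ``pre_observation`` flag set rather than as an error.
    """
    p = params
    t_star = math.log((p.c - p.x0) / p.x0) / p.a
    return InflectionSummary(
        t_star=t_star,
        x_star=p.c / 2.0,
        max_slope=p.a * p.c / 4.0,
        pre_observation=t_star <= 0.0,
    )


def mean_slope(params: LogisticParams, t1: float, t2: float) -> float:
    """Secant (average) slope (x(t2) - x(t1)) / (t2 - t1) in mm/year.

    Requires t2 > t1.
    """
    if not t2 > t1:
        raise ValueError(f"need t2 > t1, got t1={t1}, t2={t2}")
    return (imt_at_age(params, t2) - imt_at_age(params, t1)) / (t2 - t1)


def slope_profile(params: LogisticParams, age_grid: ArrayLike) -> np.ndarray:
    """Growth rate evaluated on an ordered age grid.

    Returns a (n, 2) array of (age, slope) pairs.  The grid must be
    nonempty and strictly increasing.  The profile is unimodal with its
    maximum at the grid point nearest the inflection age.
    """
    grid = np.atleast_1d(np.asarray(age_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("age_grid must be nonempty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("age_grid must be strictly increasing")
    slopes = growth_rate(params, grid)
    return np.column_stack([grid, np.atleast_1d(slopes)])
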