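"""Closed-form seasonal curve families and their phenometric primitives.

Two parametric families describe the seasonal course of a process on a
day-of-year axis:

* a skew-normal curve, ``A * (1/(omega*sqrt(2*pi))) * exp(-z**2/2) *
  (1 + erf(alpha*z/sqrt(2)))`` with ``z = (t - xi)/omega`` — a unimodal,
  possibly asymmetric peak (cambial activity, cell differentiation phases,
  starch, NEE/GPP/RECO);
* a V-type exponential, ``ymax * mu**((t - xmax)**2)`` — a symmetric curve
  with a maximum at ``xmax`` when ``mu < 1`` and a minimum when ``mu > 1``
  (soluble-sugar concentration dips), degenerating to the horizontal line
  ``y = ymax`` at ``mu = 1``.

On top of evaluation the module locates extrema, finds amplitude-percentile
crossing times on each limb, computes definite-integral areas, and derives
the maximum-activity interval (75th-percentile threshold for maxima, the
mirrored 25%-amplitude level for minima).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar
from scipy.special import erfc

__all__ = [
    "CurveFamily",
    "ExtremumType",
    "Limb",
    "SkewNormalParams",
    "VExpParams",
    "CurveSpec",
    "InvalidParameterError",
    "NumericFailureError",
    "CrossingDomainError",
    "evaluate_curve",
    "curve_extremum",
    "percentile_times",
    "curve_auc",
    "max_activity_interval",
    "search_window",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class CurveFamily(str, enum.Enum):
    SKEW_NORMAL = "skew_normal"
    V_EXPONENTIAL = "v_exponential"


class ExtremumType(str, enum.Enum):
    MAXIMUM = "maximum"
    MINIMUM = "minimum"


class Limb(str, enum.Enum):
    """Limb of a unimodal curve relative to its extremum.

    ``ASCENDING`` is the early-season side (t < t_ext) and ``DESCENDING``
    the late-season side, for minima as well as maxima: limbs are defined
    on the time axis, not on the direction of the curve's value.
    """

    ASCENDING = "ascending"
    DESCENDING = "descending"


class InvalidParameterError(ValueError):
    """A curve parameter violates its invariant (non-finite, wrong sign)."""


class NumericFailureError(RuntimeError):
    """A numeric routine (optimizer, root finder) failed to converge."""


class CrossingDomainError(ValueError):
    """A percentile level has no crossing inside the search window."""

    def __init__(self, level: float, limb: "Limb", message: str | None = None):
        self.level = level
        self.limb = limb
        super().__init__(
            message
            or f"no crossing for level {level!r} on the {limb.value} limb "
            "inside the search window"
        )


@dataclass(frozen=True)
class SkewNormalParams:
    """Skew-normal curve parameters.

    xi : location (day of year); omega : scale (days, > 0);
    alpha : shape/skew (unitless); amplitude : multiplicative height
    scale (> 0) lifting the density to the observation scale.
    """

    xi: float
    omega: float
    alpha: float
    amplitude: float = 1.0

    def __post_init__(self):
        vals = (self.xi, self.omega, self.alpha, self.amplitude)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite skew-normal parameter: {vals}")
        if self.omega <= 0:
            raise InvalidParameterError(f"omega must be > 0, got {self.omega}")
        if self.amplitude <= 0:
            raise InvalidParameterError(f"amplitude must be > 0, got {self.amplitude}")


@dataclass(frozen=True)
class VExpParams:
    """V-type exponential parameters.

    ymax : extremum height (> 0); mu : rate (> 0; maximum iff mu < 1,
    minimum iff mu > 1, horizontal line at mu = 1); xmax : extremum
    location (day of year).
    """

    ymax: float
    mu: float
    xmax: float

    def __post_init__(self):
        vals = (self.ymax, self.mu, self.xmax)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite V-exponential parameter: {vals}")
        if self.ymax <= 0:
            raise InvalidParameterError(f"ymax must be > 0, got {self.ymax}")
        if self.mu <= 0:
            raise InvalidParameterError(f"mu must be > 0, got {self.mu}")


@dataclass(frozen=True)
class CurveSpec:
    """A curve family together with its parameters."""

    family: CurveFamily
    params: SkewNormalParams | VExpParams

    def __post_init__(self):
        if self.family is CurveFamily.SKEW_NORMAL and not isinstance(
            self.params, SkewNormalParams
        ):
            raise InvalidParameterError("skew_normal spec requires SkewNormalParams")
        if self.family is CurveFamily.V_EXPONENTIAL and not isinstance(
            self.params, VExpParams
        ):
            raise InvalidParameterError("v_exponential spec requires VExpParams")

    @property
    def extremum_type(self) -> ExtremumType:
        # Classification by mu, not xmax: curvature of ymax*mu**((t-xmax)**2)
        # is governed by sign(ln mu).
        if self.family is CurveFamily.SKEW_NORMAL:
            return ExtremumType.MAXIMUM
        p = self.params
        if p.mu == 1.0:
            raise InvalidParameterError("mu = 1 gives a constant line, no extremum")
        return ExtremumType.MAXIMUM if p.mu < 1.0 else ExtremumType.MINIMUM


def _skew_normal_values(p: SkewNormalParams, t: np.ndarray) -> np.ndarray:
    z = (t - p.xi) / p.omega
    # 1 + erf(u) computed as erfc(-u): avoids catastrophic cancellation in
    # the thin tail, where 1 + erf rounds to exactly zero
    return (
        p.amplitude
        / (p.omega * _SQRT_2PI)
        * np.exp(-0.5 * z * z)
        * erfc(-p.alpha * z / math.sqrt(2.0))
    )


def _v_exp_values(p: VExpParams, t: np.ndarray) -> np.ndarray:
    s = t - p.xmax
    # clamp the exponent: far outside the season window the curve is only
    # evaluated transiently by the fitter, and inf would poison least squares
    return p.ymax * np.exp(np.minimum(math.log(p.mu) * s * s, 700.0))


def evaluate_curve(spec: CurveSpec, t):
    """Evaluate the curve at day-of-year ``t`` (scalar or array-like)."""
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("t must be finite")
    if spec.family is CurveFamily.SKEW_NORMAL:
        out = _skew_normal_values(spec.params, arr)
    else:
        out = _v_exp_values(spec.params, arr)
    if np.isscalar(t) or arr.ndim == 0:
        return float(out)
    return out


def search_window(spec: CurveSpec) -> tuple[float, float]:
    """Window bounding all practically relevant curve mass.

    Skew normal: xi +/- 6*omega.  V-exponential: xmax +/- 6/sqrt(-ln mu~)
    with mu~ = min(mu, 1/mu), the rate of the equivalent Gaussian-like
    half-width.
    """
    p = spec.params
    if spec.family is CurveFamily.SKEW_NORMAL:
        half = 6.0 * p.omega
        return (p.xi - half, p.xi + half)
    mu_t = min(p.mu, 1.0 / p.mu)
    if mu_t == 1.0:
        raise InvalidParameterError("mu = 1: constant curve has no finite window")
    half = 6.0 / math.sqrt(-math.log(mu_t))
    return (p.xmax - half, p.xmax + half)


def curve_extremum(spec: CurveSpec) -> tuple[float, float]:
    """Return ``(t_ext, value)``: the curve's interior extremum.

    The V-exponential extremum is at ``xmax`` exactly.  The skew-normal
    mode is located by bounded scalar minimization over xi +/- 6*omega to
    1e-6-day tolerance.
    """
    p = spec.params
    if spec.family is CurveFamily.V_EXPONENTIAL:
        spec.extremum_type  # raises for mu == 1
        return (p.xmax, p.ymax)
    if p.alpha == 0.0:
        return (p.xi, float(evaluate_curve(spec, p.xi)))
    lo, hi = search_window(spec)
    res = minimize_scalar(
        lambda t: -evaluate_curve(spec, t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise NumericFailureError(f"mode search failed: {res.message}")
    t_ext = float(res.x)
    margin = 1e-3 * p.omega
    if t_ext - lo < margin or hi - t_ext < margin:
        raise NumericFailureError("mode search returned a window boundary")
    return (t_ext, float(evaluate_curve(spec, t_ext)))


def _minimum_window_stats(spec: CurveSpec) -> tuple[float, float, float]:
    """(t_ext, v_min, v_max_window) for a minimum-type curve."""
    t_ext, v_min = curve_extremum(spec)
    lo, hi = search_window(spec)
    v_edge = max(float(evaluate_curve(spec, lo)), float(evaluate_curve(spec, hi)))
    return t_ext, v_min, v_edge


def _crossing_level(spec: CurveSpec, level: float) -> float:
    """Absolute curve value targeted by an activity level ``q``.

    Maximum-type: q * peak value.  Minimum-type (0-1 normalized data):
    v_min + (1 - q) * (v_max_window - v_min), so that q = 1 targets the
    extremum for both curve types and larger q always means a time closer
    to the extremum.
    """
    if spec.extremum_type is ExtremumType.MAXIMUM:
        _, v_peak = curve_extremum(spec)
        return level * v_peak
    t_ext, v_min, v_edge = _minimum_window_stats(spec)
    return v_min + (1.0 - level) * (v_edge - v_min)


def percentile_times(
    spec: CurveSpec,
    levels: Iterable[float],
    limb: Limb | str,
) -> Mapping[float, float]:
    """Crossing times of amplitude-percentile levels on one limb.

    For each level ``q`` in (0, 1], returns the unique time on the
    requested limb where the curve crosses the level's target value
    (see :func:`_crossing_level`); ``q = 1.0`` returns the extremum time.
    Bisection to 1e-6 days between the limb's outer window bound and the
    extremum.
    """
    limb = Limb(limb)
    levels = list(levels)
    for q in levels:
        if not (0.0 < q <= 1.0):
            raise ValueError(f"level must be in (0, 1], got {q}")
    t_ext, _ = curve_extremum(spec)
    lo, hi = search_window(spec)
    outer = lo if limb is Limb.ASCENDING else hi
    out: dict[float, float] = {}
    for q in levels:
        if q == 1.0:
            out[q] = t_ext
            continue
        target = _crossing_level(spec, q)

        def g(t):
            return float(evaluate_curve(spec, t)) - target

        g_outer, g_ext = g(outer), g(t_ext)
        # toward the extremum the curve approaches the peak (maxima) or the
        # minimum, so g has opposite signs at the bracket ends when the
        # level is attainable on this limb
        if g_outer * g_ext > 0:
            raise CrossingDomainError(q, limb)
        a, b = (outer, t_ext) if outer < t_ext else (t_ext, outer)
        out[q] = float(brentq(g, a, b, xtol=1e-6))
    return out


def curve_auc(spec: CurveSpec, interval: tuple[float, float]) -> float:
    """Definite integral of the curve over ``interval`` (adaptive quadrature,
    relative tolerance 1e-8)."""
    t0, t1 = interval
    if not (t0 < t1):
        raise ValueError(f"invalid interval: [{t0}, {t1}]")
    val, _ = quad(lambda t: float(evaluate_curve(spec, t)), t0, t1, epsrel=1e-8, limit=200)
    return float(val)


def max_activity_interval(spec: CurveSpec) -> tuple[float, float]:
    """Period of maximum activity.

    Maximum-type curves: the interval between the ascending and descending
    crossings of 75% of the peak value.  Minimum-type curves: the interval
    where the curve sits at or below the 25%-amplitude level
    ``v_min + 0.25 * (v_max_window - v_min)`` — the mirror of the maxima
    rule under curve inversion, i.e. activity level q = 0.75 in the
    minimum-curve level convention.
    """
    q = 0.75
    t_lo = percentile_times(spec, [q], Limb.ASCENDING)[q]
    t_hi = percentile_times(spec, [q], Limb.DESCENDING)[q]
    if not (t_lo < t_hi):
        raise NumericFailureError(f"degenerate activity interval [{t_lo}, {t_hi}]")
    return (t_lo, t_hi)
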