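"""Normalization and multi-start nonlinear least-squares curve estimation.

Observed seasonal series (cell counts, NSC concentrations, daily fluxes)
are min-max normalized to [0, 1] so that series from different sites and
units can be pooled, then fitted with one of the two parametric families in
:mod:`phenosync.curves` by least squares from a fixed, deterministic grid of
starting values.  Fit significance is an F-test of the fitted curve against
the intercept-only (constant mean) model.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import erf as _erf

from .curves import (
    CurveFamily,
    CurveSpec,
    SkewNormalParams,
    VExpParams,
    curve_extremum,
    evaluate_curve,
)

__all__ = [
    "Process",
    "Organ",
    "Biome",
    "SeasonalSeries",
    "FittedCurve",
    "DegenerateSeriesError",
    "InsufficientDataError",
    "normalize_series",
    "month_axis_to_doy",
    "fit_seasonal_curve",
    "select_curve_family",
    "MINIMUM_TYPE_PROCESSES",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_SQRT_2 = math.sqrt(2.0)

# mid-month day of year, 365-day calendar (Jan -> 15, Feb -> 46, ... Dec -> 349)
_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MID_MONTH_DOY = np.concatenate([[0], np.cumsum(_MONTH_DAYS)[:-1]]) + 15


class Process(str, enum.Enum):
    NEE = "NEE"
    GPP = "GPP"
    RECO = "RECO"
    STARCH = "starch"
    SOLUBLE_SUGARS = "soluble_sugars"
    CAMBIAL_ACTIVITY = "cambial_activity"
    CELL_ENLARGEMENT = "cell_enlargement"
    WALL_THICKENING = "wall_thickening_lignification"


class Organ(str, enum.Enum):
    NEEDLES = "needles"
    STEM = "stem"
    ROOTS = "roots"
    NONE = "none"


class Biome(str, enum.Enum):
    BOREAL = "boreal"
    TEMPERATE = "temperate"
    MEDITERRANEAN = "mediterranean"


#: processes whose seasonal curve has a minimum rather than a peak
MINIMUM_TYPE_PROCESSES = frozenset({Process.SOLUBLE_SUGARS})


class DegenerateSeriesError(ValueError):
    """Series cannot be normalized or fitted (zero range, bad axis)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested curve family."""


@dataclass
class SeasonalSeries:
    """One process/organ/site/year series on a day-of-year axis."""

    process: Process
    organ: Organ
    biome: Biome
    site_id: str
    species: str | None
    year: int | None
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise DegenerateSeriesError("times and values must be equal-length vectors")
        if len(self.times) < 6:
            raise InsufficientDataError(
                f"series needs >= 6 observations, got {len(self.times)}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise DegenerateSeriesError("times must be strictly increasing")
        if self.normalized:
            if abs(self.values.min()) > 1e-12 or abs(self.values.max() - 1.0) > 1e-12:
                raise DegenerateSeriesError("normalized series must span [0, 1]")

    @property
    def label(self) -> str:
        organ = "" if self.organ is Organ.NONE else f":{self.organ.value}"
        return f"{self.process.value}{organ}"


@dataclass
class FittedCurve:
    """A fitted seasonal curve with least-squares diagnostics."""

    spec: CurveSpec | None
    sse: float
    rse: float
    p_value: float
    n_obs: int
    converged: bool
    n_params: int = 0
    family: CurveFamily | None = None
    series: SeasonalSeries | None = field(default=None, repr=False)

    @property
    def peak_time(self) -> float:
        if self.spec is None:
            raise ValueError("no fitted spec")
        return curve_extremum(self.spec)[0]


def normalize_series(series: SeasonalSeries) -> SeasonalSeries:
    """Min-max map values to [0, 1]; times unchanged."""
    if series.normalized:
        raise ValueError("series is already normalized")
    v = series.values
    rng = v.max() - v.min()
    if rng <= 0:
        raise DegenerateSeriesError(f"constant series ({series.label}) cannot be normalized")
    return replace(series, values=(v - v.min()) / rng, normalized=True)


def month_axis_to_doy(month_indices) -> np.ndarray:
    """Map month numbers 1..12 to mid-month day of year (365-day calendar)."""
    m = np.asarray(month_indices, dtype=int)
    if np.any((m < 1) | (m > 12)):
        raise ValueError(f"month indices must be in 1..12, got {month_indices}")
    return _MID_MONTH_DOY[m - 1].astype(float)


# --- residuals and analytic jacobians -------------------------------------

def _skew_resid_jac(theta, t, y):
    xi, omega, alpha, amp = theta
    z = (t - xi) / omega
    gauss = np.exp(-0.5 * z * z)
    u = alpha * z / _SQRT_2
    E = 1.0 + _erf(u)
    C = amp / (omega * _SQRT_2PI)
    f = C * gauss * E
    dE_dz = alpha * math.sqrt(2.0 / math.pi) * np.exp(-0.5 * alpha * alpha * z * z)
    dG_dz = -z * gauss
    d_dz = C * (dG_dz * E + gauss * dE_dz)
    df_dxi = d_dz * (-1.0 / omega)
    df_domega = -f / omega + d_dz * (-z / omega)
    df_dalpha = C * gauss * math.sqrt(2.0 / math.pi) * z * np.exp(
        -0.5 * alpha * alpha * z * z
    )
    df_damp = f / amp
    J = np.column_stack([df_dxi, df_domega, df_dalpha, df_damp])
    return f - y, J


def _vexp_resid_jac(theta, t, y):
    # internal rate parameter lam = ln(mu)
    ymax, lam, xmax = theta
    s = t - xmax
    # clamp the exponent: keeps residuals and jacobian finite when a trial
    # step sends the rate far above any data-compatible value
    f = ymax * np.exp(np.minimum(lam * s * s, 50.0))
    J = np.column_stack([f / ymax, f * s * s, f * lam * (-2.0 * s)])
    return f - y, J


def _fit_one_start(resid_jac, theta0, bounds, t, y, max_nfev=500):
    with np.errstate(over="ignore", invalid="ignore"):
        return least_squares(
            lambda th: resid_jac(th, t, y)[0],
            theta0,
            jac=lambda th: resid_jac(th, t, y)[1],
            bounds=bounds,
            method="trf",
            ftol=1e-10,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=max_nfev,
        )




def _skew_starts(t, y):
    rng = t.max() - t.min()
    xis = np.quantile(t, [0.25, 0.5, 0.75])
    omegas = [rng / 10.0, rng / 4.0]
    alphas = [-5.0, 0.0, 5.0]
    starts = []
    for xi0 in xis:
        for om0 in omegas:
            a0 = max(y.max(), 1e-3) * om0 * _SQRT_2PI / 2.0
            for al0 in alphas:
                starts.append(np.array([xi0, om0, al0, a0]))
    return starts


def _vexp_starts(t, y):
    rng = t.max() - t.min()
    xs = np.quantile(t, [0.25, 0.5, 0.75])
    lams = [math.log(0.9), math.log(0.99), math.log(1.01), math.log(1.1)]
    # data-scaled shallow-rate starts for wide dips/peaks sampled over a
    # long window (|ln mu| can be ~1e-4 for monthly NSC series)
    lam_scale = math.log(20.0) / max((rng / 2.0) ** 2, 1.0)
    lams += [-lam_scale, lam_scale]
    y_hi = max(y.max(), 1e-3)
    y_lo = max(y.min(), 0.05)
    starts = []
    for x0 in xs:
        for lam0 in lams:
            ym0 = y_hi if lam0 < 0 else y_lo
            starts.append(np.array([ym0, lam0, x0]))
    return starts


def _f_test_p_value(y, sse, k):
    """F-test of the fitted curve against the constant-mean model."""
    n = len(y)
    sse0 = float(np.sum((y - y.mean()) ** 2))
    if n <= k or sse <= 0 or sse0 <= sse:
        num = max(sse0 - sse, 0.0)
    else:
        num = sse0 - sse
    if n <= k:
        return 1.0
    denom = sse / (n - k)
    if denom <= 0:
        return 0.0 if num > 0 else 1.0
    F = (num / (k - 1)) / denom
    return float(stats.f.sf(F, k - 1, n - k))


def fit_seasonal_curve(
    series: SeasonalSeries,
    family: CurveFamily | str,
    starts: Sequence[np.ndarray] | None = None,
    seed: int = 0,
) -> FittedCurve:
    """Fit one curve family to a normalized series by multi-start least squares.

    The start grid is fixed and data-derived (quantiles of the time axis,
    fractions of its range), so the result is deterministic; ``seed`` is
    accepted for interface uniformity but no stochastic perturbation of the
    starts is used.
    """
    del seed  # deterministic grid; kept for a stable call signature
    family = CurveFamily(family)
    if not series.normalized:
        raise ValueError("series must be normalized before fitting")
    t, y = series.times, series.values
    n = len(t)
    k = 4 if family is CurveFamily.SKEW_NORMAL else 3
    if n < k + 2:
        raise InsufficientDataError(
            f"{family.value} needs >= {k + 2} points, got {n}"
        )
    rng = t.max() - t.min()
    if family is CurveFamily.SKEW_NORMAL:
        resid_jac = _skew_resid_jac
        if starts is None:
            starts = _skew_starts(t, y)
        lower = [t.min() - 2 * rng, 0.5, -50.0, 1e-8]
        upper = [t.max() + 2 * rng, 10 * rng, 50.0, 1e6]
    else:
        resid_jac = _vexp_resid_jac
        if starts is None:
            starts = _vexp_starts(t, y)
        lower = [1e-8, -1.0, t.min() - 2 * rng]
        upper = [1e6, 1.0, t.max() + 2 * rng]

    best = None
    best_sse = np.inf
    any_converged = False
    for theta0 in starts:
        theta0 = np.clip(theta0, lower, upper)
        try:
            res = _fit_one_start(resid_jac, theta0, (lower, upper), t, y)
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        ok = res.status > 0
        any_converged = any_converged or ok
        if ok and sse < best_sse:
            best_sse = sse
            best = res

    if best is None:
        return FittedCurve(
            spec=None, sse=np.inf, rse=np.inf, p_value=1.0, n_obs=n,
            converged=False, n_params=k, family=family, series=series,
        )

    theta = best.x
    if family is CurveFamily.SKEW_NORMAL:
        spec = CurveSpec(
            CurveFamily.SKEW_NORMAL,
            SkewNormalParams(xi=theta[0], omega=theta[1], alpha=theta[2],
                             amplitude=theta[3]),
        )
    else:
        lam = theta[1]
        spec = CurveSpec(
            CurveFamily.V_EXPONENTIAL,
            VExpParams(ymax=theta[0], mu=math.exp(lam), xmax=theta[2]),
        )
    rse = math.sqrt(best_sse / (n - k)) if n > k else float("nan")
    p = _f_test_p_value(y, best_sse, k)
    return FittedCurve(
        spec=spec, sse=best_sse, rse=rse, p_value=p, n_obs=n,
        converged=any_converged, n_params=k, family=family, series=series,
    )


def select_curve_family(
    series: SeasonalSeries, seed: int = 0
) -> tuple[CurveFamily, FittedCurve]:
    """Family selection: skew normal first, V-exponential as fallback.

    The skew-normal fit is accepted when it converged and its extremum lies
    within [min(times) - 30, max(times) + 30] days; otherwise the
    V-exponential fit (which also covers concave/linear-like shapes) is
    returned.
    """
    skew = fit_seasonal_curve(series, CurveFamily.SKEW_NORMAL, seed=seed)
    if skew.converged and skew.spec is not None:
        try:
            t_ext = skew.peak_time
        except Exception:
            t_ext = None
        if t_ext is not None and (
            series.times.min() - 30.0 <= t_ext <= series.times.max() + 30.0
        ):
            return CurveFamily.SKEW_NORMAL, skew
    vexp = fit_seasonal_curve(series, CurveFamily.V_EXPONENTIAL, seed=seed)
    return CurveFamily.V_EXPONENTIAL, vexp
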