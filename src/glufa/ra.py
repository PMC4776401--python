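"""Empirical meal rate-of-appearance (Ra) functions.

Two parametric families describe the flux of nutrient entering the
circulation after a mixed meal, replacing mechanistic gut-absorption
models:

* **Type I** — a log-normal-like pulse with three parameters (magnitude,
  time scale, width); used for glucose and, with a fixed chylomicron lag
  t_0F, for FFA.  Total area under the curve is Delta * sqrt(2*pi).
* **Type II** — a Rayleigh-like pulse with two parameters; its total area
  equals the magnitude coefficient phi_G and its peak sits at t = tau_G.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .errors import InvalidInputError, InvalidParameterError

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _check_t(t: float) -> None:
    if t < 0:
        raise InvalidInputError(f"Ra functions are defined for t >= 0, got t={t}")


@dataclass(frozen=True)
class RaType1Glucose:
    """Log-normal-like glucose Ra: Delta_G magnitude, m_G time scale (min),
    sigma_G width (dimensionless)."""

    Delta_G: float
    m_G: float
    sigma_G: float

    def __post_init__(self) -> None:
        if self.Delta_G < 0:
            raise InvalidParameterError("Delta_G must be >= 0")
        if self.m_G <= 0 or self.sigma_G <= 0:
            raise InvalidParameterError("m_G and sigma_G must be > 0")

    def __call__(self, t: float) -> float:
        return ra_glucose_type1(t, self)

    @property
    def peak_time(self) -> float:
        """Analytic maximizer: m_G * exp(-sigma_G**2)."""
        return self.m_G * math.exp(-self.sigma_G ** 2)

    @property
    def total_auc(self) -> float:
        """Closed-form integral over [0, inf): Delta_G * sqrt(2*pi)."""
        return self.Delta_G * _SQRT2PI


@dataclass(frozen=True)
class RaType1FFA:
    """Log-normal-like FFA Ra, delayed by the chylomicron lag t_0F.

    m_F and t_0F default to the fixed convention (300 min and 60 min):
    dietary FFA does not appear in plasma until about an hour after the
    meal.
    """

    Delta_F: float
    sigma_F: float
    m_F: float = 300.0
    t_0F: float = 60.0

    def __post_init__(self) -> None:
        if self.Delta_F < 0:
            raise InvalidParameterError("Delta_F must be >= 0")
        if self.sigma_F <= 0 or self.m_F <= 0:
            raise InvalidParameterError("sigma_F and m_F must be > 0")
        if self.t_0F < 0:
            raise InvalidParameterError("t_0F must be >= 0")

    def __call__(self, t: float) -> float:
        return ra_ffa_type1(t, self)

    @property
    def total_auc(self) -> float:
        return self.Delta_F * _SQRT2PI


@dataclass(frozen=True)
class RaType2Glucose:
    """Rayleigh-like glucose Ra: phi_G magnitude, tau_G timescale (min)."""

    phi_G: float
    tau_G: float

    def __post_init__(self) -> None:
        if self.phi_G < 0:
            raise InvalidParameterError("phi_G must be >= 0")
        if self.tau_G <= 0:
            raise InvalidParameterError("tau_G must be > 0")

    def __call__(self, t: float) -> float:
        return ra_glucose_type2(t, self)

    @property
    def peak_time(self) -> float:
        return self.tau_G

    @property
    def total_auc(self) -> float:
        return self.phi_G


RaFunction = RaType1Glucose | RaType1FFA | RaType2Glucose


def _lognormal_pulse(t: float, delta: float, m: float, sigma: float) -> float:
    if t <= 0.0 or delta == 0.0:
        return 0.0
    z = math.log(t) - math.log(m)
    a = (z * z) / (2.0 * sigma * sigma)
    if a > 700.0:  # exp underflow; the prefactor cannot overflow first
        return 0.0
    return delta / (t * sigma) * math.exp(-a)


def ra_glucose_type1(t: float, p: RaType1Glucose) -> float:
    """Type I glucose Ra at time t (min); 0 at t = 0."""
    _check_t(t)
    return _lognormal_pulse(t, p.Delta_G, p.m_G, p.sigma_G)


def ra_ffa_type1(t: float, p: RaType1FFA) -> float:
    """Type I FFA Ra at time t (min); 0 for t <= t_0F."""
    _check_t(t)
    return _lognormal_pulse(t - p.t_0F, p.Delta_F, p.m_F, p.sigma_F)


def ra_glucose_type2(t: float, p: RaType2Glucose) -> float:
    """Type II glucose Ra at time t (min)."""
    _check_t(t)
    return (p.phi_G * t / p.tau_G ** 2) * math.exp(-t * t / (2.0 * p.tau_G ** 2))


def _truncation_point(ra: Callable[[float], float], t_start: float) -> float:
    """Time beyond which the pulse is negligible (< 1e-12 of its peak)."""
    grid = np.linspace(max(t_start, 0.0), max(t_start, 0.0) + 2000.0, 4001)
    peak = max(ra(float(t)) for t in grid)
    if peak == 0.0:
        return max(t_start, 0.0) + 1.0
    hi = grid[-1]
    while ra(float(hi)) > 1e-12 * peak:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - pathological widths
            break
    return float(hi)


def ra_auc(
    ra: Callable[[float], float], t_start: float, t_end: float = math.inf
) -> float:
    """Area under an Ra curve on [t_start, t_end] by adaptive quadrature.

    ``t_end = inf`` integrates the whole pulse (truncated where the
    integrand falls below 1e-12 of its peak).
    """
    if not t_start < t_end:
        raise InvalidInputError("require t_start < t_end")
    upper = _truncation_point(ra, t_start) if math.isinf(t_end) else t_end
    points = None
    if isinstance(ra, RaType1FFA) and t_start < ra.t_0F < upper:
        points = [ra.t_0F]
    val, _ = quad(ra, t_start, upper, epsabs=1e-8, limit=200, points=points)
    return float(val)
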