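"""Circular (von Mises) statistics on day-of-year data.

Phenological dates live on a circle: the last days of December are
neighbours of the first days of January.  All screening statistics in this
package therefore map days onto angles, fit the von Mises distribution
(the circular analogue of the normal, with mean direction ``mu`` and
concentration ``kappa``), and measure distances along the circle.

The year is treated as a circle of period 365.25 days uniformly across
years; at the precision of phenological event dates the sub-day mapping
error from ignoring leap-year structure is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e
from scipy.stats import vonmises as _scipy_vonmises

__all__ = [
    "DEFAULT_PERIOD",
    "KAPPA_MAX",
    "CircularSample",
    "VonMisesFit",
    "day_to_angle",
    "angle_to_day",
    "circ_dist_days",
    "vm_logpdf",
    "vm_cdf",
    "vm_central_halfwidth",
    "bessel_ratio",
    "inv_bessel_ratio",
    "vm_fit",
]

#: Days per annual cycle, applied uniformly to all years.
DEFAULT_PERIOD = 365.25

#: Concentration cap; resultant lengths above A1(KAPPA_MAX) are degenerate
#: (e.g. a constant series) and are clipped rather than allowed to overflow.
KAPPA_MAX = 500.0

_TWO_PI = 2.0 * np.pi


def day_to_angle(day, period: float = DEFAULT_PERIOD):
    """Map day-of-year values onto angles in [0, 2*pi) radians."""
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    return _TWO_PI * (np.asarray(day, dtype=float) % period) / period


def angle_to_day(angle, period: float = DEFAULT_PERIOD):
    """Inverse of :func:`day_to_angle`, returning days in [0, period)."""
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    return (np.asarray(angle, dtype=float) % _TWO_PI) * period / _TWO_PI


def circ_dist_days(d1, d2, period: float = DEFAULT_PERIOD):
    """Shortest distance in days between two dates on the annual circle.

    Wrap-aware: ``circ_dist_days(360, 10)`` is 15.25 for the default
    period, not 350.
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    diff = np.abs(np.asarray(d1, dtype=float) - np.asarray(d2, dtype=float)) % period
    return np.minimum(diff, period - diff)


@dataclass(frozen=True)
class CircularSample:
    """A series of day-of-year observations with their circular embedding."""

    days: np.ndarray
    period: float = DEFAULT_PERIOD
    angles: np.ndarray = field(init=False)

    def __post_init__(self):
        days = np.atleast_1d(np.asarray(self.days, dtype=float))
        if days.size < 1:
            raise ValueError("CircularSample requires at least one observation")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "angles", day_to_angle(days, self.period))

    def __len__(self) -> int:
        return self.days.size


@dataclass(frozen=True)
class VonMisesFit:
    """Maximum-likelihood von Mises parameters for one circular sample."""

    mu: float          # mean direction, radians in [0, 2*pi)
    kappa: float       # concentration, >= 0
    n: int             # sample size
    rbar: float        # mean resultant length in [0, 1]
    loglik: float

    def mean_day(self, period: float = DEFAULT_PERIOD) -> float:
        return float(angle_to_day(self.mu, period))


def vm_logpdf(theta, mu: float, kappa: float):
    """Log-density of the von Mises distribution.

    f(theta) = exp(kappa * cos(theta - mu)) / (2*pi*I0(kappa)); computed
    with exponentially scaled Bessel functions so large kappa is stable.
    kappa = 0 is the uniform circle, log f = -log(2*pi).
    """
    if kappa < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa}")
    theta = np.asarray(theta, dtype=float)
    return kappa * (np.cos(theta - mu) - 1.0) - np.log(_TWO_PI * i0e(kappa))


def _central_mass(delta: float, kappa: float) -> float:
    """Probability mass of the arc [mu - delta, mu + delta], delta in [0, pi]."""
    if kappa == 0.0:
        return delta / np.pi
    return float(2.0 * _scipy_vonmises.cdf(delta, kappa) - 1.0)


def vm_cdf(theta, mu: float, kappa: float):
    """CDF of the von Mises distribution on (mu - pi, mu + pi]."""
    if kappa < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa}")
    x = (np.asarray(theta, dtype=float) - mu + np.pi) % _TWO_PI - np.pi
    if kappa == 0.0:
        return (x + np.pi) / _TWO_PI
    return _scipy_vonmises.cdf(x, kappa)


def vm_central_halfwidth(kappa: float, p: float) -> float:
    """Half-width (radians) of the central interval holding mass ``p``.

    The central interval is the symmetric arc [mu - delta, mu + delta]
    about the mean direction; by symmetry of the density the half-width
    does not depend on mu.  Solved by bracketed root-finding on the
    central mass; at kappa = 0 the closed form is delta = p * pi.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if kappa < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa}")
    if kappa == 0.0:
        return p * np.pi
    return float(brentq(lambda d: _central_mass(d, kappa) - p, 0.0, np.pi,
                        xtol=1e-12, rtol=8.9e-16))


def bessel_ratio(kappa):
    """A1(kappa) = I1(kappa)/I0(kappa), the mean resultant length of VM(mu, kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    return i1e(kappa) / i0e(kappa)


def _fisher_kappa_approx(rbar: float) -> float:
    # Fisher (1993) piecewise starting value for the A1 inversion.
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    return 1.0 / (rbar**3 - 4.0 * rbar**2 + 3.0 * rbar)


def inv_bessel_ratio(rbar: float, kappa_max: float = KAPPA_MAX) -> float:
    """Invert A1 to recover kappa from a mean resultant length.

    Newton iteration from Fisher's closed-form start, using
    A1'(kappa) = 1 - A1/kappa - A1^2; falls back to bracketed Brent
    should Newton leave (0, kappa_max).  Resultant lengths at or above
    A1(kappa_max) clip to kappa_max.
    """
    if not 0.0 <= rbar <= 1.0:
        raise ValueError(f"rbar must be in [0, 1], got {rbar}")
    if rbar == 0.0:
        return 0.0
    if rbar < 1e-4:
        # small-kappa series: A1(k) = k/2 - k^3/16 + ...; Fisher's
        # approximation is already exact far below the 1e-12 tolerance
        return _fisher_kappa_approx(rbar)
    if rbar >= float(bessel_ratio(kappa_max)):
        return float(kappa_max)
    k = min(max(_fisher_kappa_approx(rbar), 1e-12), kappa_max)
    for _ in range(50):
        a = float(bessel_ratio(k))
        da = 1.0 - a / k - a * a
        if da <= 0.0:
            break
        step = (a - rbar) / da
        k_new = k - step
        if not 0.0 < k_new < kappa_max:
            break
        if abs(step) < 1e-12 * (1.0 + k_new):
            return float(k_new)
        k = k_new
    return float(brentq(lambda x: float(bessel_ratio(x)) - rbar,
                        1e-300, kappa_max, xtol=1e-12, rtol=8.9e-16))


def vm_fit(sample: CircularSample, kappa_max: float = KAPPA_MAX,
           weights=None) -> VonMisesFit:
    """Maximum-likelihood von Mises fit.

    The mean direction is the direction of the vector mean of the unit
    vectors; kappa solves A1(kappa) = rbar.  Optional non-negative
    ``weights`` give the weighted MLE used in the mixture M-step.
    """
    theta = sample.angles
    if weights is None:
        w = np.ones_like(theta)
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    c = float(np.sum(w * np.cos(theta)) / wsum)
    s = float(np.sum(w * np.sin(theta)) / wsum)
    rbar = min(float(np.hypot(c, s)), 1.0)
    mu = float(np.arctan2(s, c) % _TWO_PI) if rbar > 0 else 0.0
    kappa = inv_bessel_ratio(rbar, kappa_max=kappa_max)
    loglik = float(np.sum(w * vm_logpdf(theta, mu, kappa)))
    return VonMisesFit(mu=mu, kappa=kappa, n=int(len(theta)), rbar=rbar,
                       loglik=loglik)
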