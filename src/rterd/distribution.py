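"""Core distribution functions of the [0,1] right-truncated exponential-Rayleigh model.

The parent exponential-Rayleigh (ER) law has cumulative hazard
``H(x) = delta*x + (lam/2)*x**2`` — an exponential (linear) plus a Rayleigh
(quadratic) contribution — so its cdf is ``F(x) = 1 - exp(-H(x))`` on
``x > 0``.  Conditioning on the unit interval (right truncation at 1)
rescales by the normalizer ``Z = F(1) = 1 - exp(-(delta + lam/2))``:

    cdf(x) = (1 - exp(-(delta*x + lam*x**2/2))) / Z,       0 <= x <= 1
    pdf(x) = (delta + lam*x) * exp(-(delta*x + lam*x**2/2)) / Z

Both parameters are positive; ``delta`` acts scale-like (exponential part)
and ``lam`` shape-like (Rayleigh part).  The quantile function is available
in closed form by solving the quadratic ``lam/2 x^2 + delta x + log(1-u*Z) = 0``,
which makes inverse-transform sampling exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RTERDError",
    "ParameterError",
    "DataError",
    "DomainError",
    "ParamSet",
    "SampleData",
    "pdf",
    "cdf",
    "sf",
    "hazard",
    "quantile",
    "median",
    "rvs",
]


class RTERDError(Exception):
    """Base class for errors raised by this package."""


class ParameterError(RTERDError, ValueError):
    """Distribution parameters outside their domain (require delta, lam > 0)."""


class DataError(RTERDError, ValueError):
    """Observed data outside the support (0, 1] or otherwise invalid."""


class DomainError(RTERDError, ValueError):
    """Function argument outside its mathematical domain."""


@dataclass(frozen=True)
class ParamSet:
    """Validated parameter pair of the truncated exponential-Rayleigh law.

    Attributes
    ----------
    delta : float
        Scale-like parameter of the exponential hazard component, > 0.
    lam : float
        Shape-like parameter of the Rayleigh hazard component, > 0.
    """

    delta: float
    lam: float

    def __post_init__(self) -> None:
        d, l = float(self.delta), float(self.lam)
        if not (math.isfinite(d) and math.isfinite(l)):
            raise ParameterError(f"parameters must be finite, got ({self.delta}, {self.lam})")
        if d <= 0.0 or l <= 0.0:
            raise ParameterError(f"parameters must be positive, got ({d}, {l})")
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "lam", l)

    @property
    def Z(self) -> float:
        """Truncation normalizer ``1 - exp(-(delta + lam/2))``, always in (0, 1)."""
        return -math.expm1(-(self.delta + 0.5 * self.lam))

    def as_tuple(self) -> tuple[float, float]:
        return (self.delta, self.lam)


@dataclass(frozen=True)
class SampleData:
    """Validated vector of observations on the unit interval.

    Every value must be finite and lie in (0, 1]; zero is rejected because
    observed lifetimes are strictly positive even though the density itself
    is defined (and positive) at the origin.
    """

    values: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise DataError("sample must be a non-empty 1-d vector")
        if not np.all(np.isfinite(v)):
            raise DataError("sample contains NaN or infinite values")
        if np.any(v <= 0.0) or np.any(v > 1.0):
            bad = v[(v <= 0.0) | (v > 1.0)][0]
            raise DataError(f"observations must lie in (0, 1]; found {bad!r}")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "n", int(v.size))


def _cum_hazard(x: np.ndarray, params: ParamSet) -> np.ndarray:
    return params.delta * x + 0.5 * params.lam * x * x


def _finish(arr: np.ndarray, scalar_in: bool) -> float | np.ndarray:
    return float(arr[0]) if scalar_in else arr


def pdf(x, params: ParamSet):
    """Density ``(delta + lam*x) exp(-(delta*x + lam*x^2/2)) / Z`` on [0, 1].

    Vectorized over ``x``; returns 0 outside the support.
    """
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    out = np.zeros_like(xa)
    inside = (xa >= 0.0) & (xa <= 1.0)
    xi = xa[inside]
    out[inside] = (params.delta + params.lam * xi) * np.exp(-_cum_hazard(xi, params)) / params.Z
    return _finish(out, scalar)


def cdf(x, params: ParamSet):
    """Distribution function; 0 below the support, exactly 1 above it."""
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    out = np.zeros_like(xa)
    out[xa > 1.0] = 1.0
    inside = (xa >= 0.0) & (xa <= 1.0)
    xi = xa[inside]
    out[inside] = -np.expm1(-_cum_hazard(xi, params)) / params.Z
    return _finish(out, scalar)


def sf(x, params: ParamSet):
    """Survival function ``(exp(-H(x)) - exp(-(delta+lam/2))) / Z`` on [0, 1]."""
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    tail = math.exp(-(params.delta + 0.5 * params.lam))
    out = np.zeros_like(xa)
    out[xa < 0.0] = 1.0
    inside = (xa >= 0.0) & (xa <= 1.0)
    xi = xa[inside]
    out[inside] = (np.exp(-_cum_hazard(xi, params)) - tail) / params.Z
    return _finish(out, scalar)


def hazard(x, params: ParamSet):
    """Hazard rate pdf/sf on [0, 1); diverges (returns ``+inf``) at x = 1.

    The truncation point exhausts the survival mass, so the failure rate is
    unbounded as x approaches 1.  Arguments outside [0, 1] raise
    :class:`DomainError`.
    """
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    if np.any(xa < 0.0) or np.any(xa > 1.0):
        raise DomainError("hazard is defined on [0, 1] only")
    tail = math.exp(-(params.delta + 0.5 * params.lam))
    e = np.exp(-_cum_hazard(xa, params))
    num = (params.delta + params.lam * xa) * e
    den = e - tail
    out = np.full_like(xa, np.inf)
    ok = den > 0.0
    out[ok] = num[ok] / den[ok]
    return _finish(out, scalar)


def quantile(u, params: ParamSet):
    """Closed-form inverse cdf on [0, 1].

    Solving ``lam/2 x^2 + delta x + log1p(-u Z) = 0`` gives the positive
    quadratic root.  The textbook form ``(-delta + sqrt(delta^2 - 2 lam
    log(1-uZ))) / lam`` cancels catastrophically for small ``lam``, so the
    conjugate ("citardauq") form ``2A / (delta + sqrt(delta^2 + 2 lam A))``
    with ``A = -log1p(-u Z)`` is used; it degrades gracefully to the
    truncated-exponential inverse ``A/delta`` as ``lam -> 0``.
    """
    ua = np.asarray(u, dtype=float)
    scalar = ua.ndim == 0
    ua = np.atleast_1d(ua)
    if np.any(~np.isfinite(ua)) or np.any(ua < 0.0) or np.any(ua > 1.0):
        raise DomainError("probability levels must lie in [0, 1]")
    A = -np.log1p(-ua * params.Z)  # >= 0
    d, l = params.delta, params.lam
    out = 2.0 * A / (d + np.sqrt(d * d + 2.0 * l * A))
    return _finish(out, scalar)


def median(params: ParamSet) -> float:
    """Distribution median, the u = 1/2 quantile."""
    return float(quantile(0.5, params))


def rvs(n: int, params: ParamSet, seed) -> SampleData:
    """Draw ``n`` i.i.d. variates by inverse-transform sampling.

    Parameters
    ----------
    n : int
        Number of draws, >= 1.
    seed : int or numpy.random.Generator
        Reproducibility handle; the same seed yields bit-identical output.

    Returns
    -------
    SampleData
        All draws lie strictly inside (0, 1).
    """
    if int(n) < 1:
        raise DomainError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(int(n))
    # keep draws strictly inside the open interval
    eps = np.finfo(float).tiny
    u = np.clip(u, eps, 1.0 - np.finfo(float).epsneg)
    x = quantile(u, params)
    x = np.clip(x, np.finfo(float).tiny, 1.0 - 1e-16)
    return SampleData(values=np.atleast_1d(x))
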