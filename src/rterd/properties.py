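"""Derived mathematical properties: moments, MGF, entropy, order statistics.

Raw moments have two routes that must agree: adaptive quadrature of
``x**r * pdf(x)`` (the reference) and an alternating series obtained by
expanding the Rayleigh factor ``exp(-lam x^2/2)`` and integrating term by
term against the exponential part.  With the substitution ``y = delta*x``
each term is a pair of lower incomplete gamma functions evaluated at upper
limit ``delta`` (not 1 — the substitution maps the unit interval to
``[0, delta]``):

    M'_r = (1/Z) * sum_i (-1)^i lam^i / (2^i i!)
           * [delta * gammainc(r+2i+1, delta) + (lam/delta) * gammainc(r+2i+2, delta)]
           / delta^(r+2i+1)

The same substitution logic gives the MGF series with upper limit
``delta - t`` (the ``exp(t x)`` factor offsets the exponential hazard
term, so the series route needs ``t < delta``) and the Renyi-entropy
double series with upper limit ``eta*delta``.

The skewness and kurtosis coefficients exposed by :func:`moment_summary`
are built from RAW moments, ``M3'/(M2')^{3/2}`` and ``M4'/(M2')^2 - 3``.
These are not the conventional standardized central-moment coefficients;
the central versions are available under :func:`central_coefficients`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .distribution import DomainError, ParamSet, RTERDError, cdf, pdf, sf

__all__ = [
    "MomentSummary",
    "EntropyResult",
    "OrderStatSpec",
    "NumericalError",
    "raw_moment_quadrature",
    "raw_moment_series",
    "moment_summary",
    "central_coefficients",
    "mgf",
    "renyi_entropy",
    "renyi_entropy_series",
    "shannon_entropy",
    "order_stat_pdf",
]

#: hard cap on series terms before declaring non-convergence
_MAX_TERMS = 10_000


class NumericalError(RTERDError, ArithmeticError):
    """A series or quadrature failed to reach the requested tolerance."""


@dataclass(frozen=True)
class MomentSummary:
    """Raw moments E[X^r] for r = 1..4 and the coefficients built from them.

    ``skew_coef`` and ``kurt_coef`` are the raw-moment ratios
    ``m3/m2^1.5`` and ``m4/m2^2 - 3``; see :func:`central_coefficients`
    for the conventional central versions.
    """

    m1: float
    m2: float
    m3: float
    m4: float
    variance: float
    skew_coef: float
    kurt_coef: float


@dataclass(frozen=True)
class EntropyResult:
    """Renyi entropy value (nats) at order ``eta``."""

    eta: float
    value: float


@dataclass(frozen=True)
class OrderStatSpec:
    """Rank P out of a sample of size K, with the multinomial coefficient."""

    K: int
    P: int

    def __post_init__(self) -> None:
        if self.K < 1 or not (1 <= self.P <= self.K):
            raise DomainError(f"need 1 <= P <= K, got P={self.P}, K={self.K}")

    @property
    def coef(self) -> int:
        """K! / ((P-1)! (K-P)!)"""
        return math.factorial(self.K) // (math.factorial(self.P - 1) * math.factorial(self.K - self.P))


def raw_moment_quadrature(r: int, params: ParamSet) -> float:
    """Reference raw moment E[X^r] by adaptive quadrature on [0, 1]."""
    if int(r) < 1:
        raise DomainError(f"moment order must be >= 1, got {r}")
    val, err = integrate.quad(lambda x: x ** int(r) * pdf(x, params), 0.0, 1.0,
                              epsabs=1e-12, epsrel=1e-12)
    if err > 1e-8:
        raise NumericalError(f"moment quadrature error estimate {err:.2e} too large")
    return val


def _lower_gamma(s: float, a: float) -> float:
    """Unregularized lower incomplete gamma ``integral_0^a t^(s-1) e^-t dt``."""
    return float(special.gammainc(s, a) * special.gamma(s))


def raw_moment_series(r: int, params: ParamSet, tol: float = 1e-12) -> float:
    """Raw moment E[X^r] by the alternating incomplete-gamma series.

    Truncates once the magnitude of the next term falls below ``tol``;
    raises :class:`NumericalError` if that does not happen within the
    term cap.  Agrees with :func:`raw_moment_quadrature` to ~10*tol.
    """
    if int(r) < 1:
        raise DomainError(f"moment order must be >= 1, got {r}")
    if not (tol > 0.0):
        raise DomainError("tol must be positive")
    d, l = params.delta, params.lam
    r = int(r)
    total = 0.0
    log_coef = 0.0  # log of lam^i / (2^i i!)
    for i in range(_MAX_TERMS):
        if i > 0:
            log_coef += math.log(l / (2.0 * i))
        s = r + 2 * i + 1
        bracket = d * _lower_gamma(s, d) + (l / d) * _lower_gamma(s + 1, d)
        term = math.exp(log_coef - s * math.log(d)) * bracket
        total += term if i % 2 == 0 else -term
        if term < tol and i >= 2:
            return total / params.Z
    raise NumericalError(f"moment series did not converge within {_MAX_TERMS} terms")


def moment_summary(params: ParamSet) -> MomentSummary:
    """First four raw moments plus variance and the raw-moment coefficients."""
    m1, m2, m3, m4 = (raw_moment_quadrature(r, params) for r in (1, 2, 3, 4))
    return MomentSummary(
        m1=m1, m2=m2, m3=m3, m4=m4,
        variance=m2 - m1 * m1,
        skew_coef=m3 / m2 ** 1.5,
        kurt_coef=m4 / m2 ** 2 - 3.0,
    )


def central_coefficients(params: ParamSet) -> tuple[float, float]:
    """Conventional standardized skewness and excess kurtosis (central moments)."""
    m1, m2, m3, m4 = (raw_moment_quadrature(r, params) for r in (1, 2, 3, 4))
    var = m2 - m1 * m1
    mu3 = m3 - 3.0 * m1 * m2 + 2.0 * m1 ** 3
    mu4 = m4 - 4.0 * m1 * m3 + 6.0 * m1 ** 2 * m2 - 3.0 * m1 ** 4
    return mu3 / var ** 1.5, mu4 / var ** 2 - 3.0


def mgf(t: float, params: ParamSet, method: str = "quadrature") -> float:
    """Moment generating function E[exp(tX)].

    ``method="quadrature"`` (reference) integrates ``exp(t x) pdf(x)`` and is
    valid for every real ``t``.  ``method="series"`` evaluates the
    incomplete-gamma series, which requires ``delta - t > 0`` (the tilted
    exponent ``-(delta - t) x`` must stay negative for the lower
    incomplete gamma substitution).
    """
    t = float(t)
    if method == "quadrature":
        val, _ = integrate.quad(lambda x: math.exp(t * x) * pdf(x, params), 0.0, 1.0,
                                epsabs=1e-12, epsrel=1e-12)
        return val
    if method != "series":
        raise ValueError(f"unknown method {method!r}")
    d, l = params.delta, params.lam
    a = d - t
    if a <= 0.0:
        raise DomainError("series form of the MGF requires t < delta")
    total = 0.0
    log_coef = 0.0
    for i in range(_MAX_TERMS):
        if i > 0:
            log_coef += math.log(l / (2.0 * i))
        s = 2 * i + 1
        bracket = d * _lower_gamma(s, a) + (l / a) * _lower_gamma(s + 1, a)
        term = math.exp(log_coef - s * math.log(a)) * bracket
        total += term if i % 2 == 0 else -term
        if term < 1e-14 and i >= 2:
            return total / params.Z
    raise NumericalError(f"MGF series did not converge within {_MAX_TERMS} terms")


def renyi_entropy(eta: float, params: ParamSet) -> EntropyResult:
    """Renyi entropy ``(1-eta)^-1 log integral pdf(x)^eta dx`` by quadrature."""
    eta = float(eta)
    if eta <= 0.0 or eta == 1.0:
        raise DomainError("Renyi order must be positive and != 1; "
                          "use shannon_entropy for the eta -> 1 limit")
    val, _ = integrate.quad(lambda x: pdf(x, params) ** eta, 0.0, 1.0,
                            epsabs=1e-12, epsrel=1e-12)
    return EntropyResult(eta=eta, value=math.log(val) / (1.0 - eta))


def shannon_entropy(params: ParamSet) -> float:
    """Shannon differential entropy ``-integral pdf log pdf``, the eta -> 1 limit."""
    val, _ = integrate.quad(lambda x: -pdf(x, params) * math.log(pdf(x, params)),
                            0.0, 1.0, epsabs=1e-12, epsrel=1e-12)
    return val


def renyi_entropy_series(eta: float, params: ParamSet, tol: float = 1e-12) -> EntropyResult:
    """Renyi entropy by the double binomial/incomplete-gamma series.

    The binomial expansion of ``(delta + lam*x)^eta`` converges only where
    ``lam*x/delta < 1`` on the whole interval, so this route requires
    ``lam < delta``; quadrature (:func:`renyi_entropy`) is the reference
    everywhere.
    """
    eta = float(eta)
    if eta <= 0.0 or eta == 1.0:
        raise DomainError("Renyi order must be positive and != 1")
    d, l = params.delta, params.lam
    if not l < d:
        raise DomainError("series route requires lam < delta; use renyi_entropy")
    a = eta * d
    total = 0.0
    for j in range(_MAX_TERMS):
        binom = special.binom(eta, j)
        if binom == 0.0:
            break
        inner = 0.0
        log_p = 0.0  # log of (eta*lam/2)^p / p!
        for p in range(_MAX_TERMS):
            if p > 0:
                log_p += math.log(eta * l / (2.0 * p))
            s = 2 * p + j + 1
            term = math.exp(log_p - s * math.log(a)) * _lower_gamma(s, a)
            inner += term if p % 2 == 0 else -term
            if term < tol and p >= 2:
                break
        contrib = binom * d ** (eta - j) * l ** j * inner
        total += contrib
        if abs(contrib) < tol and j >= 2:
            break
    total /= params.Z ** eta
    return EntropyResult(eta=eta, value=math.log(total) / (1.0 - eta))


def order_stat_pdf(x, spec: OrderStatSpec, params: ParamSet):
    """Density of the P-th order statistic from a sample of size K.

    ``coef * cdf(x)^(P-1) * sf(x)^(K-P) * pdf(x)``; at P = 1 and P = K this
    reduces to the sample-minimum and sample-maximum densities.
    """
    c = float(spec.coef)
    return (c
            * np.power(cdf(x, params), spec.P - 1)
            * np.power(sf(x, params), spec.K - spec.P)
            * pdf(x, params))
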