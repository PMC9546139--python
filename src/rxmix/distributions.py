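"""Positive unimodal component families for adoption-time mixtures.

Three two-parameter families are supported behind one uniform interface:

* **Bass** — the adoption-time distribution from diffusion-of-innovation
  theory, with coefficient of innovation ``p > 0`` (spontaneous adoption
  rate) and coefficient of imitation ``q >= 0`` (adoption driven by the
  current adopter base).  Density::

      f(y | p, q) = (p+q)^2 / p * exp(-(p+q) y) / (1 + (q/p) exp(-(p+q) y))^2

* **Lognormal** — parameterized by the log-mean ``mu`` (unrestricted) and
  the log-variance ``sigma2 > 0``.  Note the second parameter is the
  *variance* of log-time, not its standard deviation.

* **Weibull** — shape ``k > 0`` and scale ``lam > 0``.

All densities have support on (0, inf); ``y = 0`` is outside the support
and rejected.  Constrained parameters map to the real line by a log
transform (``mu`` passes through) so that downstream optimization can run
unconstrained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "FAMILIES",
    "ComponentParams",
    "DomainError",
    "pdf",
    "logpdf",
    "cdf",
    "quantile",
    "mode",
    "moments",
    "sample",
    "to_unconstrained",
    "from_unconstrained",
]

FAMILIES = ("bass", "lognormal", "weibull")

#: parameter names per family, in storage order
PARAM_NAMES = {
    "bass": ("p", "q"),
    "lognormal": ("mu", "sigma2"),
    "weibull": ("k", "lam"),
}


class DomainError(ValueError):
    """Raised when a parameter or argument violates the family's domain."""


@dataclass(frozen=True)
class ComponentParams:
    """One mixture component: a family name plus its ordered parameter pair.

    Parameters are ``(p, q)`` for bass, ``(mu, sigma2)`` for lognormal and
    ``(k, lam)`` for weibull.  Validation happens at construction.
    """

    family: str
    params: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DomainError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        a, b = (float(v) for v in self.params)
        if not (np.isfinite(a) and np.isfinite(b)):
            raise DomainError(f"{self.family} parameters must be finite, got {self.params}")
        object.__setattr__(self, "params", (a, b))
        names = PARAM_NAMES[self.family]
        if self.family == "bass":
            if a <= 0:
                raise DomainError(f"bass parameter {names[0]}={a} must be > 0")
            if b < 0:
                raise DomainError(f"bass parameter {names[1]}={b} must be >= 0")
        elif self.family == "lognormal":
            if b <= 0:
                raise DomainError(f"lognormal parameter {names[1]}={b} must be > 0")
        else:  # weibull
            if a <= 0 or b <= 0:
                bad = names[0] if a <= 0 else names[1]
                raise DomainError(f"weibull parameter {bad} must be > 0, got {self.params}")
            if a < 1:
                warnings.warn(
                    f"weibull shape k={a} < 1 gives a monotone density with mode at 0; "
                    "the mixture components are intended to be unimodal on (0, inf)",
                    UserWarning,
                    stacklevel=3,
                )

    @property
    def names(self) -> Tuple[str, str]:
        return PARAM_NAMES[self.family]


def _check_y(y: np.ndarray, strict: bool = True) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if strict and np.any(y <= 0):
        raise DomainError("time y must be > 0 (support is the open positive half-line)")
    return y


def _frozen(cp: ComponentParams):
    """scipy frozen distribution for the two standard families."""
    a, b = cp.params
    if cp.family == "lognormal":
        return stats.lognorm(s=np.sqrt(b), scale=np.exp(a))
    if cp.family == "weibull":
        return stats.weibull_min(c=a, scale=b)
    raise AssertionError(cp.family)


def logpdf(cp: ComponentParams, y) -> np.ndarray:
    """Log-density, computed directly (never by logging the density).

    For the Bass family the tail term is handled through ``log1p`` of the
    decaying exponential, so the result stays finite and accurate for
    large ``(p+q)*y`` where the plain density underflows.
    """
    y = _check_y(y)
    if cp.family == "bass":
        p, q = cp.params
        s = p + q
        # log f = 2 log(s) - log(p) - s*y - 2*log(1 + (q/p) e^{-s y})
        return 2.0 * np.log(s) - np.log(p) - s * y - 2.0 * np.log1p((q / p) * np.exp(-s * y))
    # direct formulas (the scipy frozen-distribution path is far slower and
    # this is the innermost call of every likelihood evaluation)
    if cp.family == "lognormal":
        mu, s2 = cp.params
        ly = np.log(y)
        return -ly - 0.5 * np.log(2.0 * np.pi * s2) - (ly - mu) ** 2 / (2.0 * s2)
    k, lam = cp.params
    t = y / lam
    return np.log(k / lam) + (k - 1.0) * np.log(t) - t**k


def pdf(cp: ComponentParams, y) -> np.ndarray:
    """Density f(y) on (0, inf)."""
    return np.exp(logpdf(cp, y))


def cdf(cp: ComponentParams, y) -> np.ndarray:
    """Distribution function; closed form for every family.

    Bass: with E = exp(-(p+q) y),  F(y) = (1 - E) / (1 + (q/p) E).
    """
    y = _check_y(np.maximum(np.asarray(y, dtype=float), 0.0), strict=False)
    if cp.family == "bass":
        p, q = cp.params
        E = np.exp(-(p + q) * y)
        return (1.0 - E) / (1.0 + (q / p) * E)
    if cp.family == "lognormal":
        mu, s2 = cp.params
        with np.errstate(divide="ignore"):
            return special.ndtr((np.log(y) - mu) / np.sqrt(s2))
    k, lam = cp.params
    return -np.expm1(-((y / lam) ** k))


def quantile(cp: ComponentParams, u) -> np.ndarray:
    """Inverse CDF. u=0 maps to 0 and u=1 to inf for every family."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise DomainError("quantile argument u must lie in [0, 1]")
    if cp.family == "bass":
        p, q = cp.params
        with np.errstate(divide="ignore"):
            # inverting (1-E)/(1+(q/p)E) = u  for  E = e^{-(p+q)y}
            return -np.log((1.0 - u) / (1.0 + (q / p) * u)) / (p + q)
    if cp.family == "lognormal":
        mu, s2 = cp.params
        return np.exp(mu + np.sqrt(s2) * special.ndtri(u))
    k, lam = cp.params
    with np.errstate(divide="ignore"):
        return lam * (-np.log1p(-u)) ** (1.0 / k)


def mode(cp: ComponentParams) -> float:
    """Location of the maximum density (closed form for every family).

    Bass: log(q/p)/(p+q) when q > p, else 0 (density decreasing from y=0).
    Lognormal: exp(mu - sigma2).  Weibull: lam*((k-1)/k)^(1/k) for k > 1,
    else 0.
    """
    a, b = cp.params
    if cp.family == "bass":
        p, q = a, b
        if q <= p:
            return 0.0
        return float(np.log(q / p) / (p + q))
    if cp.family == "lognormal":
        return float(np.exp(a - b))
    k, lam = a, b
    if k <= 1:
        return 0.0
    return float(lam * ((k - 1.0) / k) ** (1.0 / k))


_BASS_QUAD_RTOL = 1e-8


def moments(cp: ComponentParams) -> Tuple[float, float]:
    """Return (mean, sd).

    Lognormal and Weibull use their closed forms.  The Bass family has no
    closed-form moments, so the first two raw moments are obtained by
    adaptive quadrature (relative tolerance 1e-8), splitting the range at
    the mode where the integrand peaks.
    """
    if cp.family == "lognormal":
        mu, s2 = cp.params
        mean = np.exp(mu + s2 / 2.0)
        var = (np.exp(s2) - 1.0) * np.exp(2.0 * mu + s2)
        return float(mean), float(np.sqrt(var))
    if cp.family == "weibull":
        d = _frozen(cp)
        return float(d.mean()), float(d.std())
    # bass: raw moments by quadrature
    split = max(mode(cp), 1.0 / sum(cp.params))

    def _raw(r: int) -> float:
        f = lambda y: y**r * pdf(cp, y)
        lo, err_lo = integrate.quad(f, 0.0, split, epsrel=_BASS_QUAD_RTOL, limit=200)
        hi, err_hi = integrate.quad(f, split, np.inf, epsrel=_BASS_QUAD_RTOL, limit=200)
        total, err = lo + hi, err_lo + err_hi
        if not np.isfinite(total) or (total > 0 and err / total > 1e-5):
            raise ArithmeticError(
                f"bass moment quadrature did not converge (order {r}, "
                f"value {total}, abs error {err}); parameters {cp.params}"
            )
        return total

    m1 = _raw(1)
    m2 = _raw(2)
    return float(m1), float(np.sqrt(max(m2 - m1**2, 0.0)))


def sample(cp: ComponentParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. draws by inverse-CDF on uniforms (exact and reproducible)."""
    if n < 0:
        raise DomainError("sample size must be >= 0")
    u = rng.uniform(size=n)
    return np.asarray(quantile(cp, u), dtype=float)


def to_unconstrained(cp: ComponentParams) -> np.ndarray:
    """Map the parameter pair to R^2: log for p, q, sigma2, k, lam; identity for mu."""
    a, b = cp.params
    if cp.family == "lognormal":
        return np.array([a, np.log(b)])
    if cp.family == "bass" and b == 0.0:
        raise DomainError("bass q=0 lies on the boundary and has no unconstrained image")
    return np.array([np.log(a), np.log(b)])


def from_unconstrained(family: str, v) -> ComponentParams:
    """Inverse of :func:`to_unconstrained`."""
    v = np.asarray(v, dtype=float)
    if v.shape != (2,):
        raise DomainError(f"expected a length-2 vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise DomainError(f"unconstrained parameters must be finite, got {v}")
    if family == "lognormal":
        return ComponentParams(family, (float(v[0]), float(np.exp(v[1]))))
    return ComponentParams(family, (float(np.exp(v[0])), float(np.exp(v[1]))))
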