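"""Closed-form math for candidate failure-time distributions.

The log-logistic distribution is the fully featured core: its *scale*
parameter ``a`` equals the median failure time and its *shape* parameter
``k`` controls the spread of log failure times through the identity
``var[log t_f] = pi^2 / (3 k^2)``.  Larger ``k`` means a more switch-like
decline of cumulative survival; ``k`` in the range 1-3 (typical for
insects near their thermal limits) gives a long right tail of failure
times.

Four alternative families (exponential, Weibull, log-normal, Gompertz)
are provided through :func:`family_log_density` for model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LogLogisticParams",
    "FamilyParams",
    "FAMILIES",
    "survival_probability",
    "failure_density",
    "hazard_rate",
    "quantile",
    "variance_of_log_failure_time",
    "sample_failure_times",
    "log_density",
    "family_log_density",
    "family_n_params",
]

FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal", "gompertz")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "loglogistic": 2,
    "lognormal": 2,
    "gompertz": 2,
}


@dataclass(frozen=True)
class LogLogisticParams:
    """Log-logistic parameters: ``scale`` (minutes, equals the median
    failure time) and ``shape`` (dimensionless)."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be positive and finite, got {self.scale}")
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValueError(f"shape must be positive and finite, got {self.shape}")

    @property
    def median(self) -> float:
        return self.scale


@dataclass(frozen=True)
class FamilyParams:
    """Parameters for one of the five candidate families.

    Parameter order per family (all times in minutes):

    - ``exponential``: (rate,) with rate = 1 / mean failure time
    - ``weibull``: (scale, shape)
    - ``loglogistic``: (scale, shape), same meaning as :class:`LogLogisticParams`
    - ``lognormal``: (mu, sigma) of log failure time (natural log)
    - ``gompertz``: (shape, rate) with hazard h(t) = rate * exp(shape * t);
      shape may be any real, rate > 0 (conventions differ across sources,
      hence documented here)
    """

    family: str
    params: Sequence[float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        n = _N_PARAMS[self.family]
        if len(self.params) != n:
            raise ValueError(
                f"{self.family} takes {n} parameter(s), got {len(self.params)}"
            )
        if self.family == "exponential" and self.params[0] <= 0:
            raise ValueError("exponential rate must be > 0")
        if self.family in ("weibull", "loglogistic") and (
            self.params[0] <= 0 or self.params[1] <= 0
        ):
            raise ValueError(f"{self.family} scale and shape must be > 0")
        if self.family == "lognormal" and self.params[1] <= 0:
            raise ValueError("lognormal sigma must be > 0")
        if self.family == "gompertz" and self.params[1] <= 0:
            raise ValueError("gompertz rate must be > 0")


def family_n_params(family: str) -> int:
    if family not in _N_PARAMS:
        raise ValueError(f"unknown family {family!r}")
    return _N_PARAMS[family]


def _check_nonneg(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError("failure time t must be nonnegative")


def survival_probability(t, p: LogLogisticParams):
    """Cumulative survival S(t) = (1 + (t/a)^k)^(-1).

    S(0) = 1, S(scale) = 0.5, and S decreases to 0 as t grows.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg(t)
    with np.errstate(divide="ignore"):
        z = p.shape * (np.log(t) - np.log(p.scale))  # -inf at t=0
    out = np.exp(-np.logaddexp(0.0, z))
    return out if out.ndim else float(out)


def log_density(t, p: LogLogisticParams):
    """Natural log of the failure density f(t); -inf where f vanishes."""
    t = np.asarray(t, dtype=float)
    _check_nonneg(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.log(t)
        z = p.shape * (logt - math.log(p.scale))
        out = math.log(p.shape) + z - logt - 2.0 * np.logaddexp(0.0, z)
    # t == 0: density is 0 for k > 1, k/a for k == 1, +inf for k < 1
    if np.any(t == 0):
        at0 = math.inf if p.shape < 1 else (
            math.log(p.shape / p.scale) if p.shape == 1 else -math.inf
        )
        out = np.where(t == 0, at0, out)
    return out if out.ndim else float(out)


def failure_density(t, p: LogLogisticParams):
    """Failure density f(t) = -dS/dt = (k/a)(t/a)^(k-1) (1+(t/a)^k)^(-2)."""
    out = np.exp(log_density(t, p))
    return out if np.ndim(out) else float(out)


def hazard_rate(t, p: LogLogisticParams):
    """Hazard h(t) = f(t)/S(t) = (k/a)(t/a)^(k-1) / (1+(t/a)^k).

    Unimodal (rises then falls) for k > 1; monotone decreasing for k <= 1.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg(t)
    if np.any((t == 0) & (p.shape < 1)):
        raise ValueError("hazard diverges at t=0 when shape < 1")
    with np.errstate(divide="ignore"):
        logt = np.log(t)
        z = p.shape * (logt - math.log(p.scale))
        out = np.exp(math.log(p.shape) + z - logt - np.logaddexp(0.0, z))
    if np.any(t == 0):
        out = np.where(t == 0, 0.0 if p.shape > 1 else 1.0 / p.scale, out)
    return out if out.ndim else float(out)


def quantile(prob_surviving, p: LogLogisticParams):
    """Time t at which S(t) equals ``prob_surviving``.

    t = a * ((1-q)/q)^(1/k); the median (q=0.5) equals the scale.
    """
    q = np.asarray(prob_surviving, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("prob_surviving must lie strictly inside (0, 1)")
    out = p.scale * ((1.0 - q) / q) ** (1.0 / p.shape)
    return out if out.ndim else float(out)


def variance_of_log_failure_time(shape: float) -> float:
    """Variance of log(t_f) for a log-logistic with the given shape:
    pi^2 / (3 k^2).  Decreases to 0 as k grows (a point mass at the scale)."""
    if not (shape > 0):
        raise ValueError("shape must be > 0")
    return math.pi**2 / (3.0 * shape**2)


def sample_failure_times(p: LogLogisticParams, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. failure times by inverse-CDF sampling.

    ``seed`` is an int or a numpy Generator; identical seeds give
    identical vectors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=int(n))  # survival probabilities
    return p.scale * ((1.0 - u) / u) ** (1.0 / p.shape)


def family_log_density(fp: FamilyParams, t):
    """Log failure density under the named family.

    The exponential family has constant hazard lambda; Weibull with
    shape 1 reduces to it; the log-logistic branch agrees with
    :func:`log_density`.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg(t)
    f = fp.family
    with np.errstate(divide="ignore", invalid="ignore"):
        if f == "exponential":
            (lam,) = fp.params
            out = math.log(lam) - lam * t
        elif f == "weibull":
            scale, shape = fp.params
            logt = np.log(t)
            z = shape * (logt - math.log(scale))
            out = math.log(shape) + z - logt - np.exp(z)
            if np.any(t == 0):
                at0 = (
                    -math.log(scale)
                    if shape == 1
                    else (math.inf if shape < 1 else -math.inf)
                )
                out = np.where(t == 0, at0, out)
        elif f == "loglogistic":
            out = log_density(t, LogLogisticParams(*fp.params))
        elif f == "lognormal":
            mu, sigma = fp.params
            logt = np.log(t)
            out = (
                -logt
                - math.log(sigma)
                - 0.5 * math.log(2 * math.pi)
                - 0.5 * ((logt - mu) / sigma) ** 2
            )
            if np.any(t == 0):
                out = np.where(t == 0, -math.inf, out)
        else:  # gompertz
            shape, rate = fp.params
            # h(t) = rate e^{shape t};  H(t) = rate (e^{shape t}-1)/shape
            if abs(shape) < 1e-12:
                out = math.log(rate) - rate * t
            else:
                out = math.log(rate) + shape * t - (rate / shape) * np.expm1(shape * t)
    return out if out.ndim else float(out)
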