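"""Fitting thermal-death-time (TDT) models to constant-temperature data.

Workflow mirrors how static knockdown assays are analysed: filter out
under-sized trials, fit a log-logistic to each species x temperature
cell, regress log median failure time on temperature (the TDT line),
and optionally fit all records jointly with an accelerated-failure-time
(AFT) model whose log scale is linear in temperature and whose shape is
constant or itself temperature-linked.  Model families are compared by
AIC, and two diagnostics probe the assumptions: a likelihood-ratio test
for a shape-temperature trend and a likelihood-ratio test for
non-proportional hazards.

All maximum-likelihood fits run in unconstrained coordinates (log scale,
log shape) with a quasi-Newton optimizer and three starts (moment-based,
median-based, perturbed); the log-logistic family uses analytic
gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distributions import FAMILIES

__all__ = [
    "FailureRecord",
    "FailureDataset",
    "FilterResult",
    "CellFit",
    "TDTRegression",
    "ShapeTrend",
    "AFTFitResult",
    "PHTestResult",
    "NoDataError",
    "DegenerateDataError",
    "FitError",
    "filter_min_trial_size",
    "fit_cell",
    "fit_cells",
    "fit_tdt_regression",
    "fit_aft_model",
    "rank_families_by_aic",
    "test_shape_trend",
    "test_ph_nonconstancy",
]

COLUMNS = ["species", "sex", "temperature_C", "time_min", "trial_id"]


class NoDataError(ValueError):
    """No records remain after filtering/validation."""


class DegenerateDataError(ValueError):
    """Data admit no interior maximum-likelihood solution."""


class FitError(RuntimeError):
    """Optimizer failed in a way that invalidates the result."""


@dataclass(frozen=True)
class FailureRecord:
    """One individual's failure (knockdown) time at a constant assay
    temperature."""

    species: str
    temperature: float
    failure_time: float
    trial_id: str = "trial0"
    sex: str | None = None

    def __post_init__(self) -> None:
        if not (self.failure_time > 0):
            raise ValueError(f"failure_time must be > 0, got {self.failure_time}")
        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")


class FailureDataset:
    """Individual failure-time records, grouped by species x temperature
    (cells) and, within cells, by trial."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in ("species", "temperature_C", "time_min", "trial_id") if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        frame = frame.copy()
        if "sex" not in frame.columns:
            frame["sex"] = None
        if len(frame) == 0:
            raise NoDataError("dataset is empty")
        if (frame["time_min"] <= 0).any():
            bad = frame.index[frame["time_min"] <= 0].tolist()
            raise ValueError(f"nonpositive time_min at row index {bad}")
        if not np.isfinite(frame["temperature_C"]).all():
            raise ValueError("non-finite temperature_C")
        self._frame = frame[COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[FailureRecord]) -> "FailureDataset":
        return cls(
            pd.DataFrame(
                {
                    "species": [r.species for r in records],
                    "sex": [r.sex for r in records],
                    "temperature_C": [r.temperature for r in records],
                    "time_min": [r.failure_time for r in records],
                    "trial_id": [r.trial_id for r in records],
                }
            )
        )

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def species(self) -> list[str]:
        return sorted(self._frame["species"].unique())

    @property
    def temperatures(self) -> np.ndarray:
        return np.sort(self._frame["temperature_C"].unique())

    def cells(self):
        """Yield ((species, temperature), sub-frame) per cell."""
        for key, g in self._frame.groupby(["species", "temperature_C"], sort=True):
            yield key, g

    def trials(self):
        for key, g in self._frame.groupby(
            ["species", "temperature_C", "trial_id"], sort=True
        ):
            yield key, g

    def subset(self, mask) -> "FailureDataset":
        return FailureDataset(self._frame[mask])


@dataclass
class FilterResult:
    dataset: FailureDataset
    dropped: pd.DataFrame  # columns species, temperature_C, trial_id, n


def filter_min_trial_size(data: FailureDataset, min_n: int = 10) -> FilterResult:
    """Drop (species, temperature, trial) groups with fewer than ``min_n``
    individuals; small trials make shape estimates unstable.

    Returns the filtered dataset together with a report of dropped groups.
    Record order is preserved.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    frame = data.frame
    sizes = frame.groupby(["species", "temperature_C", "trial_id"], sort=False)[
        "time_min"
    ].transform("size")
    keep = sizes >= min_n
    dropped = (
        frame[~keep]
        .groupby(["species", "temperature_C", "trial_id"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    if not keep.any():
        raise NoDataError(
            f"no data after filtering at min_n={min_n}; "
            f"{len(dropped)} group(s) dropped"
        )
    return FilterResult(FailureDataset(frame[keep]), dropped)


# ---------------------------------------------------------------------------
# log-logistic ML machinery (analytic gradients)
# ---------------------------------------------------------------------------


def _ll_negloglik_grad(theta, Xa, Xk, logt, linear_shape=False):
    """NLL and gradient for a log-logistic AFT with design matrices Xa
    (log scale) and Xk (shape link)."""
    na = Xa.shape[1]
    loga = Xa @ theta[:na]
    eta = Xk @ theta[na:]
    if linear_shape:
        k = eta
        if np.any(k <= 0):
            return np.inf, np.zeros_like(theta)
        logk = np.log(k)
    else:
        logk = eta
        k = np.exp(np.clip(logk, -40, 40))
    w = logt - loga
    z = k * w
    # loglik_i = log k + k w - log t - 2 log(1 + e^z)
    ll = logk + z - logt - 2.0 * np.logaddexp(0.0, z)
    sig = 0.5 * (1.0 + np.tanh(0.5 * z))  # sigmoid(z), stable
    dll_dloga = k * (2.0 * sig - 1.0)
    if linear_shape:
        dll_dk = 1.0 / k + w * (1.0 - 2.0 * sig)
        gk = Xk.T @ dll_dk
    else:
        dll_dlogk = 1.0 + z * (1.0 - 2.0 * sig)
        gk = Xk.T @ dll_dlogk
    grad = np.concatenate([Xa.T @ dll_dloga, gk])
    return -float(np.sum(ll)), -grad


def _num_hessian(grad: Callable, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        step = eps * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += step
        xm = x.copy(); xm[i] -= step
        H[:, i] = (grad(xp) - grad(xm)) / (2 * step)
    return 0.5 * (H + H.T)


def _minimize_multistart(fun, starts, jac=None, gtol=1e-8):
    """Quasi-Newton minimisation from several starts; returns the best
    converged result, or the best overall flagged as non-converged.

    BFGS sometimes stops with "precision loss" at a perfectly good
    optimum; a result also counts as converged when its gradient is
    tiny relative to the objective.
    """
    best = None
    best_conv = None
    for x0 in starts:
        try:
            # objectives return +inf outside the parameter space, which
            # makes the line search emit benign overflow warnings
            with np.errstate(all="ignore"):
                res = optimize.minimize(
                    fun, np.asarray(x0, float), jac=jac, method="BFGS",
                    options={"gtol": gtol, "maxiter": 500},
                )
        except (FloatingPointError, ValueError):
            continue
        if not np.isfinite(res.fun):
            continue
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        ok = res.success or gnorm < 1e-4 * max(1.0, abs(res.fun))
        if best is None or res.fun < best.fun:
            best = res
        if ok and (best_conv is None or res.fun < best_conv.fun):
            best_conv = res
    if best_conv is not None:
        return best_conv, True, ""
    if best is None:
        raise FitError("all optimizer starts failed")
    return best, False, str(best.message)


def _loglogistic_starts(logt, Tc, with_slope, with_shape_slope, linear_shape):
    """Moment-based, median-based and perturbed starts in fit coordinates."""
    if with_slope:
        b1, b0 = np.polyfit(Tc, logt, 1)
        resid = logt - (b0 + b1 * Tc)
    else:
        b0, b1 = float(np.mean(logt)), 0.0
        resid = logt - b0
    v = max(float(np.var(resid)), 1e-6)
    k0 = math.pi / math.sqrt(3.0 * v)  # invert var[log t] = pi^2/(3k^2)
    med = float(np.median(logt - (b1 * Tc if with_slope else 0.0)))

    def pack(b0_, k_):
        loc = [b0_, b1] if with_slope else [b0_]
        sh = [k_ if linear_shape else math.log(k_)]
        if with_shape_slope:
            sh.append(0.0)
        return np.array(loc + sh)

    starts = [pack(b0, k0), pack(med, k0)]
    starts.append(starts[0] + 0.3 * np.ones_like(starts[0]))
    return starts


# ---------------------------------------------------------------------------
# per-cell fits and the TDT regression
# ---------------------------------------------------------------------------


@dataclass
class CellFit:
    """Log-logistic ML fit for one species x temperature cell."""

    species: str
    temperature: float
    n: int
    scale_hat: float
    shape_hat: float
    log_scale_se: float
    shape_se: float
    loglik: float
    converged: bool = True
    message: str = ""


def fit_cell(
    times: Sequence[float],
    species: str = "",
    temperature: float = float("nan"),
) -> CellFit:
    """Maximum-likelihood log-logistic fit to one cell's failure times.

    Standard errors come from the observed information (numerical Hessian
    of the negative log-likelihood at the optimum).  All-identical times
    push the shape to infinity and raise :class:`DegenerateDataError`.
    """
    t = np.asarray(times, dtype=float)
    if len(t) < 2 or len(np.unique(t)) < 2:
        raise DegenerateDataError(
            "need >= 2 distinct failure times (identical times imply shape -> inf)"
        )
    if np.any(t <= 0):
        raise ValueError("failure times must be > 0")
    logt = np.log(t)
    ones = np.ones((len(t), 1))
    fun = lambda th: _ll_negloglik_grad(th, ones, ones, logt)
    starts = _loglogistic_starts(logt, np.zeros(len(t)), False, False, False)
    res, conv, msg = _minimize_multistart(lambda th: fun(th)[0], starts,
                                          jac=lambda th: fun(th)[1])
    b0, lk = res.x
    H = _num_hessian(lambda th: fun(th)[1], res.x)
    try:
        cov = np.linalg.inv(H)
        se_b0 = math.sqrt(max(cov[0, 0], 0.0))
        se_lk = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_b0 = se_lk = float("nan")
        conv, msg = False, msg or "singular observed information"
    shape = math.exp(lk)
    return CellFit(
        species=species,
        temperature=float(temperature),
        n=len(t),
        scale_hat=math.exp(b0),
        shape_hat=shape,
        log_scale_se=se_b0,
        shape_se=shape * se_lk,  # delta method from log-shape
        loglik=-res.fun,
        converged=conv,
        message=msg,
    )


def fit_cells(data: FailureDataset) -> list[CellFit]:
    """Independent per-cell log-logistic fits (one per species x
    temperature, trials pooled)."""
    out = []
    for (species, temp), g in data.cells():
        out.append(fit_cell(g["time_min"].to_numpy(), species=species, temperature=temp))
    return out


@dataclass
class TDTRegression:
    """The TDT line: log median failure time = intercept + slope * T."""

    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    temperatures: np.ndarray

    def median_at(self, temperature) -> np.ndarray | float:
        """Predicted median failure time t50(T) in minutes."""
        out = np.exp(self.intercept + self.slope * np.asarray(temperature, float))
        return out if out.ndim else float(out)


def fit_tdt_regression(cells, medians=None) -> TDTRegression:
    """Ordinary least squares of log median failure time on temperature.

    ``cells`` is either a list of :class:`CellFit` (the fitted scale is
    the median) or an array of temperatures, in which case ``medians``
    supplies the matching median failure times in minutes.
    """
    if medians is None:
        fits = list(cells)
        T = np.array([c.temperature for c in fits], float)
        y = np.log([c.scale_hat for c in fits])
    else:
        T = np.asarray(cells, float)
        y = np.log(np.asarray(medians, float))
    if len(np.unique(T)) < 2:
        raise ValueError("TDT regression needs >= 2 distinct temperatures")
    slope, intercept = np.polyfit(T, y, 1)
    resid = y - (intercept + slope * T)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return TDTRegression(float(slope), float(intercept), r2, resid, T)


# ---------------------------------------------------------------------------
# joint AFT fits across temperatures
# ---------------------------------------------------------------------------

SHAPE_LINKS = ("constant", "log-linear", "linear")


@dataclass
class AFTFitResult:
    """Joint ML fit of one family with location linear in temperature.

    ``coefficients`` holds ``beta0``/``beta1`` (location intercept/slope,
    log-minutes and per degC) and the shape-link coefficients ``gamma0``
    (and ``gamma1`` when the shape is temperature-linked).  For the
    log-linked families gamma parameterises log(shape); for the Gompertz
    it is the (real) shape itself; for the log-normal it is log(sigma).
    """

    family: str
    shape_link: str
    coefficients: dict[str, float]
    se: dict[str, float]
    loglik: float
    aic: float
    n: int
    converged: bool = True
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


def _family_negloglik(family, shape_link, theta, t, T, logt):
    """Generic NLL: location linear in T, shape constant or linked.

    Returns +inf for parameter values that overflow or leave the
    parameter space, so the optimizer backs away from them.
    """
    with np.errstate(all="ignore"):
        b0, b1 = theta[0], theta[1]
        loc = b0 + b1 * T
        if family == "exponential":
            lam = np.exp(-loc)  # mean failure time exp(loc)
            nll = -np.sum(-loc - lam * t)
        else:
            g = theta[2:]
            eta = g[0] + (g[1] * T if len(g) > 1 else 0.0)
            if family == "weibull":
                k = np.exp(eta) if shape_link != "linear" else eta
                if np.any(k <= 0):
                    return np.inf
                z = k * (logt - loc)
                nll = -np.sum(np.log(k) + z - logt - np.exp(z))
            elif family == "lognormal":
                sig = np.exp(eta) if shape_link != "linear" else eta
                if np.any(sig <= 0):
                    return np.inf
                r = (logt - loc) / sig
                nll = -np.sum(
                    -logt - np.log(sig) - 0.5 * math.log(2 * math.pi) - 0.5 * r**2
                )
            elif family == "gompertz":
                # h(t) = rate e^{s t}; shape s real (identity link), s < 0
                # gives a defective tail as in standard survival software
                s = np.broadcast_to(np.asarray(eta, float), t.shape)
                rate = np.exp(-loc)
                small = np.abs(s) < 1e-12
                s_safe = np.where(small, 1.0, s)
                H = np.where(small, rate * t, rate / s_safe * np.expm1(s * t))
                nll = -np.sum(-loc + s * t - H)
            else:
                raise ValueError(f"unknown family {family!r}")
        nll = float(nll)
        return nll if math.isfinite(nll) else np.inf


def fit_aft_model(
    data: FailureDataset,
    family: str = "loglogistic",
    shape_link: str = "constant",
) -> AFTFitResult:
    """Joint ML over all records: location (log scale) linear in
    temperature; shape constant, log-linear in T, or linear in T.

    The exponential family has no shape and admits no link.  Fitting runs
    on temperature centred at its mean for conditioning; reported
    coefficients are transformed back to the plain degC parameterisation.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if family == "exponential" and shape_link != "constant":
        raise ValueError("exponential has no shape parameter to link")
    if shape_link not in SHAPE_LINKS:
        raise ValueError(f"shape_link must be one of {SHAPE_LINKS}")
    frame = data.frame
    t = frame["time_min"].to_numpy(float)
    T = frame["temperature_C"].to_numpy(float)
    if len(np.unique(T)) < 2:
        raise ValueError("AFT fit needs >= 2 distinct temperatures")
    logt = np.log(t)
    Tbar = float(T.mean())
    Tc = T - Tbar
    linked = shape_link != "constant"
    linear_shape = shape_link == "linear"

    if family == "loglogistic":
        n_obs = len(t)
        Xa = np.column_stack([np.ones(n_obs), Tc])
        Xk = np.column_stack([np.ones(n_obs)] + ([Tc] if linked else []))
        fg = lambda th: _ll_negloglik_grad(th, Xa, Xk, logt, linear_shape)
        starts = _loglogistic_starts(logt, Tc, True, linked, linear_shape)
        res, conv, msg = _minimize_multistart(
            lambda th: fg(th)[0], starts, jac=lambda th: fg(th)[1]
        )
        grad = lambda th: fg(th)[1]
    else:
        if family == "exponential":
            n_free = 2
        else:
            n_free = 3 + (1 if linked else 0)
        b1, b0 = np.polyfit(Tc, logt, 1)
        v = max(float(np.var(logt - b0 - b1 * Tc)), 1e-6)
        k0 = math.pi / math.sqrt(3.0 * v)
        base = [b0, b1]
        if family == "weibull":
            base += [k0 if linear_shape else math.log(k0)]
        elif family == "lognormal":
            s0 = math.sqrt(v)
            base += [s0 if linear_shape else math.log(s0)]
        elif family == "gompertz":
            base += [0.0]
        if linked and family != "exponential":
            base += [0.0]
        base = np.array(base[:n_free])
        fun = lambda th: _family_negloglik(family, shape_link, th, t, Tc, logt)
        if family == "gompertz":
            # shape starts scaled to the data's time span
            s_scale = 1.0 / float(np.mean(t))
            starts = []
            for s0 in (1e-8, 0.5 * s_scale, -0.5 * s_scale):
                st = base.copy()
                st[2] = s0
                starts.append(st)
        else:
            starts = [base, base + 0.2, base - 0.2]
        res, conv, msg = _minimize_multistart(fun, starts)
        grad = None

    theta = res.x
    names = ["beta0", "beta1"]
    if family != "exponential":
        names.append("gamma0")
        if linked:
            names.append("gamma1")
    # observed information in centred coordinates
    if grad is None:
        g_num = lambda x: optimize.approx_fprime(x, lambda th:
            _family_negloglik(family, shape_link, th, t, Tc, logt), 1e-6)
        H = _num_hessian(g_num, theta, eps=1e-4)
    else:
        H = _num_hessian(grad, theta)
    try:
        cov_c = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_c = np.full((len(theta), len(theta)), np.nan)
        conv, msg = False, msg or "singular observed information"

    # de-centre: intercepts absorb slope * Tbar
    coef = dict(zip(names, theta))
    J = np.eye(len(theta))
    coef["beta0"] = coef["beta0"] - coef["beta1"] * Tbar
    J[0, 1] = -Tbar
    if "gamma1" in coef:
        i0, i1 = names.index("gamma0"), names.index("gamma1")
        coef["gamma0"] = coef["gamma0"] - coef["gamma1"] * Tbar
        J[i0, i1] = -Tbar
    cov = J @ cov_c @ J.T
    se = {nm: float(np.sqrt(max(cov[i, i], 0.0))) if np.isfinite(cov[i, i]) else float("nan")
          for i, nm in enumerate(names)}
    loglik = -float(res.fun)
    k_free = len(names)
    return AFTFitResult(
        family=family,
        shape_link=shape_link if family != "exponential" else "constant",
        coefficients={k: float(v) for k, v in coef.items()},
        se=se,
        loglik=loglik,
        aic=2.0 * k_free - 2.0 * loglik,
        n=len(t),
        converged=conv,
        message=msg,
    )


def rank_families_by_aic(
    data: FailureDataset, shape_link: str = "constant"
) -> pd.DataFrame:
    """Fit all five families (location linear in temperature, shape
    constant unless linked) and rank them from lowest AIC (rank 1) to
    highest.

    Ties are broken by fewer parameters, then family name.  A family
    that fails to converge is flagged and excluded from ranking.
    """
    rows = []
    for fam in FAMILIES:
        link = "constant" if fam == "exponential" else shape_link
        try:
            r = fit_aft_model(data, family=fam, shape_link=link)
            rows.append(
                dict(family=fam, n_params=r.n_params, loglik=r.loglik,
                     aic=r.aic, converged=r.converged, message=r.message)
            )
        except (FitError, ValueError) as exc:
            rows.append(dict(family=fam, n_params=np.nan, loglik=np.nan,
                             aic=np.nan, converged=False, message=str(exc)))
    table = pd.DataFrame(rows)
    ok = table["converged"] & table["aic"].notna()
    # AIC differences below 1e-9 are ties, broken by parsimony then name
    table["_aic_key"] = np.round(table["aic"] * 1e9) / 1e9
    ranked = table[ok].sort_values(["_aic_key", "n_params", "family"]).reset_index()
    table["rank"] = pd.NA
    for rank, idx in enumerate(ranked["index"], start=1):
        table.loc[idx, "rank"] = rank
    return (
        table.drop(columns="_aic_key").sort_values("family").reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ShapeTrend:
    """Likelihood-ratio test of a temperature trend in the log-logistic
    shape (H0: gamma1 = 0)."""

    gamma0: float
    gamma1: float
    lr_statistic: float
    df: int
    p_value: float
    loglik_full: float
    loglik_reduced: float


def _pooled_loglogistic_fit(frame: pd.DataFrame, with_shape_slope: bool):
    """Species-specific intercepts for log-scale and log-shape, shared
    temperature slopes; returns (negloglik, theta, names)."""
    t = frame["time_min"].to_numpy(float)
    logt = np.log(t)
    T = frame["temperature_C"].to_numpy(float)
    Tc = T - T.mean()
    sp = pd.Categorical(frame["species"])
    S = len(sp.categories)
    D = np.eye(S)[sp.codes]  # dummies
    Xa = np.column_stack([D, Tc])
    Xk = np.column_stack([D] + ([Tc] if with_shape_slope else []))
    fg = lambda th: _ll_negloglik_grad(th, Xa, Xk, logt)
    # starts from the pooled single-species recipe, replicated per species
    b1, b0 = np.polyfit(Tc, logt, 1)
    v = max(float(np.var(logt - b0 - b1 * Tc)), 1e-6)
    lk0 = math.log(math.pi / math.sqrt(3.0 * v))
    base = np.concatenate([np.full(S, b0), [b1], np.full(S, lk0),
                           [0.0] if with_shape_slope else []])
    starts = [base, base + 0.2, base - 0.2]
    res, conv, msg = _minimize_multistart(lambda th: fg(th)[0], starts,
                                          jac=lambda th: fg(th)[1])
    if not conv:
        raise FitError(f"pooled fit did not converge: {msg}")
    return -res.fun, res.x, S, float(T.mean())


def test_shape_trend(
    data: FailureDataset, pooling: str = "per-species"
) -> ShapeTrend | dict[str, ShapeTrend]:
    """LR test of whether the log-logistic shape changes with temperature.

    ``per-species``: each species tested on its own (df = 1); a dict is
    returned when the dataset holds several species.  ``pooled``:
    species-specific intercepts for log-scale and log-shape with shared
    temperature slopes, one common gamma1 (df = 1) — a fixed-effects
    stand-in for a random-intercept formulation.
    """
    if pooling not in ("per-species", "pooled"):
        raise ValueError("pooling must be 'per-species' or 'pooled'")
    if pooling == "per-species":
        out = {}
        for species in data.species:
            sub = data.subset(data.frame["species"] == species)
            if len(np.unique(sub.frame["temperature_C"])) < 3:
                raise ValueError(
                    f"species {species!r}: shape-trend test needs >= 3 temperatures"
                )
            full = fit_aft_model(sub, "loglogistic", shape_link="log-linear")
            red = fit_aft_model(sub, "loglogistic", shape_link="constant")
            out[species] = _shape_trend_from(full, red)
        return out if len(out) > 1 else next(iter(out.values()))
    # pooled
    if len(np.unique(data.frame["temperature_C"])) < 3:
        raise ValueError("shape-trend test needs >= 3 temperatures")
    ll_full, th_full, S, Tbar = _pooled_loglogistic_fit(data.frame, True)
    ll_red, _, _, _ = _pooled_loglogistic_fit(data.frame, False)
    lr = 2.0 * (ll_full - ll_red)
    if lr < -1e-6:
        raise FitError("reduced model beat the full model; optimizer failure")
    lr = max(lr, 0.0)
    g1 = float(th_full[-1])
    g0_centred = float(np.mean(th_full[S + 1 : 2 * S + 1]))
    return ShapeTrend(
        gamma0=g0_centred - g1 * Tbar,
        gamma1=g1,
        lr_statistic=lr,
        df=1,
        p_value=float(stats.chi2.sf(lr, 1)),
        loglik_full=float(ll_full),
        loglik_reduced=float(ll_red),
    )


def _shape_trend_from(full: AFTFitResult, red: AFTFitResult) -> ShapeTrend:
    lr = 2.0 * (full.loglik - red.loglik)
    if lr < -1e-6:
        raise FitError("reduced model beat the full model; optimizer failure")
    lr = max(lr, 0.0)
    return ShapeTrend(
        gamma0=full.coefficients["gamma0"],
        gamma1=full.coefficients["gamma1"],
        lr_statistic=lr,
        df=1,
        p_value=float(stats.chi2.sf(lr, 1)),
        loglik_full=full.loglik,
        loglik_reduced=red.loglik,
    )


@dataclass
class PHTestResult:
    statistic: float
    df: int
    p_value: float
    loglik_full: float
    loglik_reduced: float


def _weibull_ph_negloglik(theta, t, Tc, logt, with_interaction):
    """Weibull-baseline PH: h(t|T) = p lam t^(p-1) exp(th1 T + th2 T log t)."""
    loglam, logp, th1 = theta[0], theta[1], theta[2]
    th2 = theta[3] if with_interaction else 0.0
    p = math.exp(logp)
    q = p + th2 * Tc  # time exponent of the cumulative hazard
    if np.any(q <= 1e-8):
        return np.inf
    logh = loglam + logp + (p - 1.0) * logt + th1 * Tc + th2 * Tc * logt
    with np.errstate(over="raise"):
        try:
            H = math.exp(loglam) * p * np.exp(th1 * Tc + q * logt) / q
        except FloatingPointError:
            return np.inf
    if not np.all(np.isfinite(H)):
        return np.inf
    return -float(np.sum(logh - H))


def test_ph_nonconstancy(data: FailureDataset, min_per_temp: int = 3) -> PHTestResult:
    """LR test of the proportional-hazards assumption across temperatures.

    Compares a Weibull-baseline PH model with temperature as covariate
    against the same model with a temperature x log(time) interaction
    (df = 1).  A large statistic means hazard ratios between temperatures
    drift over time — PH does not hold, as expected when the survival
    curve's shape itself changes with temperature.
    """
    frame = data.frame
    T = frame["temperature_C"].to_numpy(float)
    if len(np.unique(T)) < 2:
        raise ValueError("PH test needs >= 2 temperatures")
    counts = frame.groupby("temperature_C").size()
    if (counts < min_per_temp).any():
        raise ValueError(
            f"insufficient events per temperature (min {min_per_temp}): "
            f"{counts[counts < min_per_temp].to_dict()}"
        )
    t = frame["time_min"].to_numpy(float)
    logt = np.log(t)
    Tc = T - T.mean()
    b1, b0 = np.polyfit(Tc, logt, 1)
    v = max(float(np.var(logt - b0 - b1 * Tc)), 1e-6)
    p0 = math.pi / math.sqrt(6.0 * v)  # Weibull: var[log t] = pi^2/(6 p^2)
    lam0 = math.exp(-p0 * b0)
    base_red = np.array([math.log(max(lam0, 1e-12)), math.log(p0), -p0 * b1])

    fun_red = lambda th: _weibull_ph_negloglik(th, t, Tc, logt, False)
    res_r, conv_r, msg_r = _minimize_multistart(
        fun_red, [base_red, base_red + 0.2, base_red - 0.2]
    )
    if not conv_r:
        raise FitError(f"reduced PH fit did not converge: {msg_r}")
    base_full = np.append(res_r.x, 0.0)
    fun_full = lambda th: _weibull_ph_negloglik(th, t, Tc, logt, True)
    res_f, conv_f, msg_f = _minimize_multistart(
        fun_full, [base_full, base_full + 0.1, base_full - 0.1]
    )
    if not conv_f:
        raise FitError(f"full PH fit did not converge: {msg_f}")
    lr = 2.0 * (res_r.fun - res_f.fun)
    if lr < -1e-6:
        raise FitError("interaction model fit worse than nested null")
    lr = max(lr, 0.0)
    return PHTestResult(
        statistic=float(lr),
        df=1,
        p_value=float(stats.chi2.sf(lr, 1)),
        loglik_full=-float(res_f.fun),
        loglik_reduced=-float(res_r.fun),
    )
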