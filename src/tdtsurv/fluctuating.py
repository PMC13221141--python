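"""Survival prediction under fluctuating stressful temperatures.

Three predictors share a damage-accumulation backbone but differ in what
they assume about variation in failure times:

- **Jorgensen** (deterministic additive damage): injury accrues at rate
  1/t50(T); the median failure time is the first time accumulated damage
  reaches 1.  No survival curve.
- **Rezende** (pooled average survival curve): one empirical survival
  curve in relative time r = t / t50(T), pooled over all constant
  temperatures, evaluated at accumulated relative time.
- **Increasing variance** (parametric log-logistic): log scale declines
  linearly with temperature and shape is itself temperature-linked, so
  the spread of failure times can grow as temperature rises.  At constant
  temperature the prediction is exactly the static log-logistic curve.

All times are minutes, temperatures degrees Celsius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .static_fit import AFTFitResult, FailureDataset, TDTRegression

__all__ = [
    "TemperatureProfile",
    "LogLogisticTDTModel",
    "DamageTrajectory",
    "AverageRelativeCurve",
    "SurvivalPrediction",
    "MedianEstimate",
    "LogLikelihoodResult",
    "accumulate_damage",
    "predict_median_jorgensen",
    "build_average_relative_curve",
    "predict_survival_rezende",
    "predict_survival_increasing_variance",
    "profile_log_likelihood",
]

DEFAULT_GRID_STEP = 0.1  # minutes
DEFAULT_HORIZON_MULTIPLIER = 10.0
SHAPE_MODES = ("instantaneous", "duration-weighted")


@dataclass(frozen=True)
class TemperatureProfile:
    """Time-indexed temperature trajectory T(t).

    ``interpolation='stepwise'`` holds ``temperatures[i]`` on
    ``[times[i], times[i+1])`` (chamber setpoints); ``'linear'``
    interpolates between knots.  Beyond the last knot the final
    temperature is held.
    """

    times: np.ndarray
    temperatures: np.ndarray
    interpolation: str = "stepwise"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        temp = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or temp.shape != t.shape or len(t) < 1:
            raise ValueError("times and temperatures must be 1-D, same length >= 1")
        if t[0] != 0:
            raise ValueError("profile must start at time 0")
        t, idx = np.unique(t, return_index=True)
        temp = temp[idx]
        if self.interpolation not in ("stepwise", "linear"):
            raise ValueError("interpolation must be 'stepwise' or 'linear'")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", temp)

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def temperature_at(self, t):
        t = np.asarray(t, dtype=float)
        if self.interpolation == "stepwise":
            idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, None)
            out = self.temperatures[idx]
        else:
            out = np.interp(t, self.times, self.temperatures)
        return out if out.ndim else float(out)

    def temperature_range(self) -> tuple[float, float]:
        return float(self.temperatures.min()), float(self.temperatures.max())

    @classmethod
    def constant(cls, temperature: float) -> "TemperatureProfile":
        return cls(np.array([0.0]), np.array([float(temperature)]))

    @classmethod
    def stepwise(cls, durations: Sequence[float], temps: Sequence[float]) -> "TemperatureProfile":
        """Build from segment (duration, temperature) pairs."""
        durations = np.asarray(durations, float)
        if np.any(durations <= 0):
            raise ValueError("segment durations must be > 0")
        knots = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(knots, np.asarray(temps, float))


@dataclass(frozen=True)
class LogLogisticTDTModel:
    """Temperature-linked log-logistic: log a(T) = beta0 + beta1 T and
    log k(T) = gamma0 + gamma1 T (gamma1 = 0 gives constant shape).

    ``fitted_range`` optionally records the temperature span of the
    static data; predictions outside it warn about extrapolation.
    """

    beta0: float
    beta1: float
    gamma0: float
    gamma1: float = 0.0
    fitted_range: tuple[float, float] | None = None

    def scale_at(self, T):
        out = np.exp(self.beta0 + self.beta1 * np.asarray(T, float))
        return out if out.ndim else float(out)

    def shape_at(self, T):
        out = np.exp(self.gamma0 + self.gamma1 * np.asarray(T, float))
        return out if out.ndim else float(out)

    @classmethod
    def from_aft_fit(cls, fit: AFTFitResult,
                     fitted_range: tuple[float, float] | None = None
                     ) -> "LogLogisticTDTModel":
        if fit.family != "loglogistic":
            raise ValueError(f"expected a loglogistic fit, got {fit.family}")
        if fit.shape_link == "linear":
            raise ValueError("linear shape link has no log-linear equivalent")
        c = fit.coefficients
        return cls(
            beta0=c["beta0"], beta1=c["beta1"],
            gamma0=c["gamma0"], gamma1=c.get("gamma1", 0.0),
            fitted_range=fitted_range,
        )


def _warn_extrapolation(profile: TemperatureProfile, fitted_range) -> None:
    if fitted_range is None:
        return
    lo, hi = profile.temperature_range()
    dist = max(fitted_range[0] - lo, hi - fitted_range[1], 0.0)
    if dist > 0:
        warnings.warn(
            f"profile extends {dist:.2f} degC beyond the fitted temperature "
            f"range {fitted_range}; temperature links are extrapolated",
            stacklevel=3,
        )


@dataclass
class DamageTrajectory:
    """Accumulated damage D(t) = integral of rate(T(u)) du, piecewise
    linear between grid/knot times."""

    times: np.ndarray
    damage: np.ndarray

    def __post_init__(self) -> None:
        if self.damage[0] != 0:
            raise ValueError("damage must start at 0")
        if np.any(np.diff(self.damage) < -1e-12):
            raise ValueError("damage must be nondecreasing")

    def damage_at(self, t):
        out = np.interp(t, self.times, self.damage)
        return out if np.ndim(out) else float(out)

    def first_time_reaching(self, level: float) -> float | None:
        """First t with D(t) = level (exact on the piecewise-linear
        trajectory), or None if never reached."""
        if level <= 0:
            return 0.0
        idx = np.searchsorted(self.damage, level, side="left")
        if idx >= len(self.damage):
            return None
        if idx == 0:
            return float(self.times[0])
        d0, d1 = self.damage[idx - 1], self.damage[idx]
        t0, t1 = self.times[idx - 1], self.times[idx]
        if d1 == d0:
            return float(t1)
        return float(t0 + (level - d0) / (d1 - d0) * (t1 - t0))


def accumulate_damage(
    profile: TemperatureProfile,
    rate_at_temperature: Callable[[np.ndarray], np.ndarray],
    t_end: float | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
) -> DamageTrajectory:
    """Integrate a temperature-dependent damage rate along a profile.

    Stepwise profiles are integrated in closed form (exact piecewise
    linear); linearly interpolated profiles use the trapezoid rule on a
    grid of ``grid_step`` minutes.  Additivity means segment order does
    not change total damage.
    """
    if t_end is None:
        t_end = profile.duration
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if profile.interpolation == "stepwise":
        knots = profile.times[profile.times < t_end]
        ts = np.append(knots, t_end)
        rates = np.asarray(rate_at_temperature(profile.temperatures[: len(knots)]), float)
        for i, r in enumerate(np.atleast_1d(rates)):
            if not (np.isfinite(r) and r > 0):
                raise ValueError(
                    f"non-finite or nonpositive rate {r} on segment {i} "
                    f"(T={profile.temperatures[i]} degC)"
                )
        seg = np.atleast_1d(rates) * np.diff(ts)
        damage = np.concatenate([[0.0], np.cumsum(seg)])
        return DamageTrajectory(ts, damage)
    n = max(int(math.ceil(t_end / grid_step)), 1)
    ts = np.linspace(0.0, t_end, n + 1)
    rates = np.asarray(rate_at_temperature(profile.temperature_at(ts)), float)
    if not np.all(np.isfinite(rates) & (rates > 0)):
        bad = int(np.argmax(~(np.isfinite(rates) & (rates > 0))))
        raise ValueError(
            f"non-finite or nonpositive rate at t={ts[bad]:.3f} min "
            f"(T={profile.temperature_at(ts[bad]):.3f} degC)"
        )
    damage = np.concatenate([[0.0], np.cumsum(0.5 * (rates[1:] + rates[:-1]) * np.diff(ts))])
    return DamageTrajectory(ts, damage)


@dataclass
class MedianEstimate:
    """Predicted median failure time; ``beyond_horizon`` flags a median
    not reached within the search horizon."""

    minutes: float
    beyond_horizon: bool = False
    horizon: float = float("nan")


def _horizon(profile: TemperatureProfile, median_at_coolest: float,
             multiplier: float) -> float:
    return max(multiplier * median_at_coolest, profile.duration, 1.0)


def predict_median_jorgensen(
    profile: TemperatureProfile,
    tdt: TDTRegression,
    horizon_multiplier: float = DEFAULT_HORIZON_MULTIPLIER,
    grid_step: float = DEFAULT_GRID_STEP,
) -> MedianEstimate:
    """Deterministic additive-damage median: first t with
    D(t) = integral 1/t50(T(u)) du = 1.

    At constant temperature this is exactly t50(T).  The search horizon
    defaults to ``horizon_multiplier`` times the constant-temperature
    median at the profile's coolest temperature.
    """
    lo, _ = profile.temperature_range()
    t50_cool = tdt.median_at(lo)
    if not (np.isfinite(t50_cool) and t50_cool > 0):
        raise ValueError(f"nonpositive predicted t50 at {lo} degC")
    horizon = _horizon(profile, t50_cool, horizon_multiplier)
    traj = accumulate_damage(
        profile, lambda T: 1.0 / tdt.median_at(T), t_end=horizon, grid_step=grid_step
    )
    t_med = traj.first_time_reaching(1.0)
    if t_med is None:
        return MedianEstimate(float("nan"), beyond_horizon=True, horizon=horizon)
    return MedianEstimate(t_med, horizon=horizon)


# ---------------------------------------------------------------------------
# pooled average relative survival curve (Rezende-style)
# ---------------------------------------------------------------------------


class AverageRelativeCurve:
    """Empirical survival curve in relative time r = t_f / t50(T_assay),
    pooled across all constant-temperature assays.

    ``empirical_survival`` is the right-continuous step estimate;
    ``evaluate`` passes linearly through each jump's midpoint (the smooth
    version used by the predictor).  ``density`` is a kernel estimate on
    log r (Silverman's rule by default).
    """

    def __init__(self, pooled_r: Sequence[float], bandwidth: float | str = "silverman"):
        r = np.sort(np.asarray(pooled_r, dtype=float))
        if len(r) == 0:
            raise ValueError("empty pool of relative failure times")
        if np.any(r <= 0):
            raise ValueError("relative failure times must be > 0")
        self.pooled_r = r
        n = len(r)
        v, counts = np.unique(r, return_counts=True)
        cum = np.cumsum(counts)
        # survival through the midpoint of each jump
        mid_S = 1.0 - (cum - counts / 2.0) / n
        self.relative_times = v
        self.survival = mid_S
        if len(v) > 1:
            self._kde = stats.gaussian_kde(np.log(r), bw_method=bandwidth)
            # evaluate once on a dense log-r grid; density() interpolates
            bw = float(self._kde.factor * np.std(np.log(r), ddof=1))
            u = np.linspace(math.log(v[0]) - 6 * bw, math.log(v[-1]) + 6 * bw, 2048)
            self._dens_u = u
            self._dens_g = self._kde(u)
        else:
            self._kde = None

    @property
    def n(self) -> int:
        return len(self.pooled_r)

    def empirical_survival(self, r):
        """Right-continuous step survival: fraction of pooled r above r."""
        r = np.asarray(r, dtype=float)
        out = 1.0 - np.searchsorted(self.pooled_r, r, side="right") / self.n
        return out if out.ndim else float(out)

    def evaluate(self, r):
        """Piecewise-linear survival through jump midpoints; 1 before the
        first observation, linearly extrapolated to 0 after the last."""
        r = np.asarray(r, dtype=float)
        v, S = self.relative_times, self.survival
        if len(v) == 1:
            out = np.where(r < v[0], 1.0, 0.0)
            return out if out.ndim else float(out)
        slope = (S[-1] - S[-2]) / (v[-1] - v[-2])
        if slope < 0:
            v_end = v[-1] - S[-1] / slope
        else:
            v_end = v[-1] * (1.0 + 1e-9) + 1e-9
        vx = np.concatenate([v, [v_end]])
        Sx = np.concatenate([S, [0.0]])
        out = np.interp(r, vx, Sx, left=1.0, right=0.0)
        out = np.where(r < v[0], 1.0, out)
        return out if out.ndim else float(out)

    def density(self, r):
        """Kernel density of pooled r (estimated on the log scale and
        interpolated from a dense cached grid)."""
        r = np.asarray(r, dtype=float)
        if self._kde is None:
            out = np.zeros_like(r)
            return out if out.ndim else float(out)
        with np.errstate(divide="ignore"):
            u = np.log(np.maximum(r, 1e-300))
        g = np.interp(u, self._dens_u, self._dens_g, left=0.0, right=0.0)
        out = np.where(r > 0, g / np.maximum(r, 1e-300), 0.0)
        return out if out.ndim else float(out)


def build_average_relative_curve(
    data: FailureDataset,
    tdt: TDTRegression,
    bandwidth: float | str = "silverman",
) -> AverageRelativeCurve:
    """Rescale every observed failure time by its assay temperature's
    predicted median and pool across temperatures."""
    frame = data.frame
    if len(np.unique(frame["temperature_C"])) < 2:
        raise ValueError("average relative curve needs >= 2 assay temperatures")
    r = frame["time_min"].to_numpy(float) / tdt.median_at(
        frame["temperature_C"].to_numpy(float)
    )
    return AverageRelativeCurve(r, bandwidth=bandwidth)


# ---------------------------------------------------------------------------
# survival predictions under a profile
# ---------------------------------------------------------------------------


@dataclass
class SurvivalPrediction:
    """Predicted survival along a profile: S and f on a time grid plus
    the derived median failure time."""

    times: np.ndarray
    survival: np.ndarray
    density: np.ndarray
    median_tf: float
    model_label: str
    beyond_horizon: bool = False
    grid_step: float = DEFAULT_GRID_STEP
    metadata: dict = field(default_factory=dict)

    def survival_at(self, t):
        out = np.interp(t, self.times, self.survival)
        return out if np.ndim(out) else float(out)

    def density_at(self, t):
        out = np.interp(t, self.times, self.density)
        return out if np.ndim(out) else float(out)


def _fd_density(times: np.ndarray, survival: np.ndarray) -> np.ndarray:
    """Central finite differences of -S; negative values clipped at 0."""
    d = -np.gradient(survival, times)
    return np.clip(d, 0.0, None)


def _bisect_median(S_of_t: Callable[[float], float], t_lo: float, t_hi: float,
                   tol: float = 1e-6) -> float:
    while t_hi - t_lo > tol:
        mid = 0.5 * (t_lo + t_hi)
        if S_of_t(mid) > 0.5:
            t_lo = mid
        else:
            t_hi = mid
    return 0.5 * (t_lo + t_hi)


def _median_from_grid(times, survival, S_of_t) -> tuple[float, bool]:
    below = np.nonzero(survival <= 0.5)[0]
    if len(below) == 0:
        return float("nan"), True
    i = int(below[0])
    if i == 0:
        return float(times[0]), False
    return _bisect_median(S_of_t, float(times[i - 1]), float(times[i])), False


def predict_survival_rezende(
    profile: TemperatureProfile,
    curve: AverageRelativeCurve,
    tdt: TDTRegression,
    grid_step: float = DEFAULT_GRID_STEP,
    horizon_multiplier: float = DEFAULT_HORIZON_MULTIPLIER,
) -> SurvivalPrediction:
    """Average-curve prediction: accumulated relative time
    R(t) = integral du / t50(T(u)) maps the profile onto the pooled
    curve, S(t) = C(R(t)).

    At constant temperature this is the average curve stretched by
    t50(T).  The density is the curve's kernel estimate transported to
    the time axis, f(t) = g(R(t)) / t50(T(t)): finite differences of the
    raw pooled step curve would hand the model a log-density whose local
    jitter systematically depresses its likelihood (plug-in bias), which
    is a property of the estimator, not of the model being scored.
    """
    lo, _ = profile.temperature_range()
    horizon = _horizon(profile, float(tdt.median_at(lo)), horizon_multiplier)
    traj = accumulate_damage(
        profile, lambda T: 1.0 / tdt.median_at(T), t_end=horizon, grid_step=grid_step
    )
    n = max(int(math.ceil(horizon / grid_step)), 1)
    times = np.linspace(0.0, horizon, n + 1)
    R = traj.damage_at(times)
    S = curve.evaluate(R)
    density = curve.density(R) / np.asarray(
        tdt.median_at(profile.temperature_at(times)), float
    )
    med, beyond = _median_from_grid(
        times, S, lambda t: float(curve.evaluate(traj.damage_at(t)))
    )
    return SurvivalPrediction(
        times=times, survival=S, density=density,
        median_tf=med, model_label="rezende", beyond_horizon=beyond,
        grid_step=grid_step,
    )


def predict_survival_increasing_variance(
    profile: TemperatureProfile,
    model: LogLogisticTDTModel,
    grid_step: float = DEFAULT_GRID_STEP,
    horizon_multiplier: float = DEFAULT_HORIZON_MULTIPLIER,
    shape_mode: str = "instantaneous",
) -> SurvivalPrediction:
    """Increasing-variance log-logistic prediction.

    Scaled damage D_a(t) = integral du / a(T(u)) plays the role of t/a;
    survival is S(t) = (1 + D_a(t)^k)^(-1) with the shape k evaluated at
    the instantaneous temperature k(T(t)) (default) or as the
    duration-weighted mean of k(T(u)) up to t.  At constant temperature
    both reduce exactly to the static log-logistic curve with
    (a(T), k(T)).
    """
    if shape_mode not in SHAPE_MODES:
        raise ValueError(f"shape_mode must be one of {SHAPE_MODES}")
    for v in (model.beta0, model.beta1, model.gamma0, model.gamma1):
        if not math.isfinite(v):
            raise ValueError("model coefficients must be finite")
    _warn_extrapolation(profile, model.fitted_range)
    lo, _ = profile.temperature_range()
    horizon = _horizon(profile, float(model.scale_at(lo)), horizon_multiplier)
    traj = accumulate_damage(
        profile, lambda T: 1.0 / model.scale_at(T), t_end=horizon, grid_step=grid_step
    )
    n = max(int(math.ceil(horizon / grid_step)), 1)
    times = np.linspace(0.0, horizon, n + 1)
    D = traj.damage_at(times)

    if shape_mode == "instantaneous":
        def k_at(t):
            return model.shape_at(profile.temperature_at(t))
    else:  # duration-weighted mean of k(T(u)) on [0, t]
        ktraj = accumulate_damage(
            profile, lambda T: model.shape_at(T), t_end=horizon, grid_step=grid_step
        )

        def k_at(t):
            t = np.asarray(t, float)
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.where(t > 0, ktraj.damage_at(t) / np.maximum(t, 1e-300),
                               model.shape_at(profile.temperature_at(0.0)))
            return out if out.ndim else float(out)

    def S_raw(t):
        t = np.asarray(t, float)
        d = traj.damage_at(t)
        k = np.asarray(k_at(t), float)
        with np.errstate(divide="ignore"):
            z = k * np.log(np.maximum(d, 1e-300))
        out = np.where(d <= 0, 1.0, np.exp(-np.logaddexp(0.0, z)))
        return out if out.ndim else float(out)

    # A drop in k(T(t)) at a segment boundary can push the raw curve
    # upward, but realized mortality is irreversible: clamp survival to
    # its running minimum so S is a valid (nonincreasing) curve.
    S_grid_raw = np.asarray(S_raw(times))
    S = np.minimum.accumulate(S_grid_raw)

    def S_cont(t: float) -> float:
        # bisection evaluator: exact raw curve where the clamp is not
        # binding, grid interpolation inside clamped stretches
        i = int(np.searchsorted(times, t))
        i = min(max(i, 1), len(times) - 1)
        if S[i - 1] == S_grid_raw[i - 1] and S[i] == S_grid_raw[i]:
            return min(float(S_raw(t)), float(S[i - 1]))
        return float(np.interp(t, times, S))

    med, beyond = _median_from_grid(times, S, S_cont)
    return SurvivalPrediction(
        times=times, survival=S, density=_fd_density(times, S),
        median_tf=med, model_label="increasing_variance", beyond_horizon=beyond,
        grid_step=grid_step, metadata={"shape_mode": shape_mode},
    )


@dataclass
class LogLikelihoodResult:
    """Summed log density of observed failure times under a prediction;
    densities below the floor are counted in ``n_floored``."""

    loglik: float
    n_floored: int
    n: int

    def __float__(self) -> float:
        return self.loglik


def profile_log_likelihood(
    prediction: SurvivalPrediction,
    observed_times: Sequence[float],
    floor: float = 1e-12,
) -> LogLikelihoodResult:
    """Sum of log predicted failure density at each observed time.

    Density is linearly interpolated on the prediction grid and floored
    at ``floor`` per minute so a stray observation in a zero-density
    region cannot send the sum to -inf.
    """
    obs = np.asarray(observed_times, dtype=float)
    if obs.size == 0:
        raise ValueError("no observed times")
    if np.any(obs < prediction.times[0]) or np.any(obs > prediction.times[-1]):
        raise ValueError(
            "observed time outside the prediction grid; re-run the "
            "prediction with a larger horizon_multiplier"
        )
    dens = np.interp(obs, prediction.times, prediction.density)
    n_floored = int(np.sum(dens < floor))
    return LogLikelihoodResult(
        loglik=float(np.sum(np.log(np.maximum(dens, floor)))),
        n_floored=n_floored,
        n=len(obs),
    )
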