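"""Synthetic static and fluctuating knockdown datasets.

The generator emulates the statistical structure the models assume: at
constant temperature, failure times are log-logistic with
log a(T) = beta0 + beta1 T and log k(T) = gamma0 + gamma1 T; under a
fluctuating profile, failure times are drawn from the increasing-
variance prediction by inverse-CDF sampling.  Defaults are set to a
realistic knockdown regime: medians fall from roughly 18 hours at 33 degC
to about 2 minutes at 40 degC (TDT slope -0.9 per degC on the natural-log
scale) while the shape drops from about 5 to about 1.5, and fluctuating
profiles stay within the stressful 34-42 degC band.

Sub-seeds derive from the root seed by a fixed counter scheme
(``SeedSequence([seed, stream, index])`` with stream 1 for static cells
keyed by deci-degrees, 2 for profiles and 3 for per-set draws), so
adding a temperature or a set never changes other cells' draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .compare import SetObservation
from .distributions import LogLogisticParams, sample_failure_times
from .fluctuating import (
    LogLogisticTDTModel,
    TemperatureProfile,
    predict_survival_increasing_variance,
)
from .static_fit import FailureDataset

__all__ = [
    "SimulationConfig",
    "StaticSimulation",
    "generate_static_dataset",
    "generate_temperature_profile",
    "sample_under_profile",
    "generate_fluctuating_sets",
]

PROFILE_KINDS = ("constant", "step", "ramp", "sinusoid")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator (see module docstring for the
    rationale behind the defaults)."""

    temperatures: tuple[float, ...] = tuple(float(T) for T in range(33, 41))
    n_per_cell: int = 20
    beta0: float = 36.7
    beta1: float = -0.9
    gamma0: float = 7.2
    gamma1: float = -0.17
    n_sets: int = 26
    n_per_set: int = 20
    profile_kind: str = "step"
    profile_bounds: tuple[float, float] = (34.0, 42.0)
    stressful_range: tuple[float, float] = (32.5, 45.0)
    segment_minutes: tuple[float, float] = (20.0, 60.0)
    n_segments: tuple[int, int] = (2, 4)
    ramp_minutes: tuple[float, float] = (120.0, 240.0)
    sinusoid_period: float = 60.0
    sinusoid_resolution: float = 1.0
    species: str = "sim_species"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1 or self.n_sets < 1 or self.n_per_set < 1:
            raise ValueError("all counts must be >= 1")
        if len(self.temperatures) < 1:
            raise ValueError("need at least one temperature")
        lo, hi = self.profile_bounds
        slo, shi = self.stressful_range
        if not (slo <= lo < hi <= shi):
            raise ValueError(
                f"profile bounds {self.profile_bounds} must lie within the "
                f"declared stressful range {self.stressful_range}"
            )
        if self.profile_kind not in PROFILE_KINDS:
            raise ValueError(f"profile_kind must be one of {PROFILE_KINDS}")

    @property
    def model(self) -> LogLogisticTDTModel:
        """The true temperature-linked log-logistic behind the draws."""
        return LogLogisticTDTModel(
            beta0=self.beta0, beta1=self.beta1,
            gamma0=self.gamma0, gamma1=self.gamma1,
        )


@dataclass
class StaticSimulation:
    dataset: FailureDataset
    truth: LogLogisticTDTModel
    config: SimulationConfig


def _cell_rng(seed: int, temperature: float) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), 1, int(round(temperature * 10)) + 10_000])
    )


def generate_static_dataset(cfg: SimulationConfig) -> StaticSimulation:
    """Draw ``n_per_cell`` log-logistic failure times at every
    temperature; deterministic given the config seed, cell by cell."""
    records = {"species": [], "sex": [], "temperature_C": [], "time_min": [],
               "trial_id": []}
    model = cfg.model
    for T in cfg.temperatures:
        rng = _cell_rng(cfg.seed, T)
        p = LogLogisticParams(scale=model.scale_at(T), shape=model.shape_at(T))
        t = sample_failure_times(p, cfg.n_per_cell, rng)
        records["species"] += [cfg.species] * cfg.n_per_cell
        records["sex"] += [None] * cfg.n_per_cell
        records["temperature_C"] += [float(T)] * cfg.n_per_cell
        records["time_min"] += list(t)
        records["trial_id"] += ["trial0"] * cfg.n_per_cell
    import pandas as pd

    return StaticSimulation(
        dataset=FailureDataset(pd.DataFrame(records)), truth=model, config=cfg
    )


def generate_temperature_profile(cfg: SimulationConfig, set_index: int) -> TemperatureProfile:
    """One assay profile of the configured kind, inside the configured
    temperature bounds; deterministic given (seed, set_index)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2, int(set_index)]))
    lo, hi = cfg.profile_bounds
    kind = cfg.profile_kind
    if kind == "constant":
        return TemperatureProfile.constant(rng.uniform(lo, hi))
    if kind == "step":
        n_seg = int(rng.integers(cfg.n_segments[0], cfg.n_segments[1] + 1))
        durations = rng.uniform(*cfg.segment_minutes, size=n_seg)
        temps = rng.uniform(lo, hi, size=n_seg)
        return TemperatureProfile.stepwise(durations, temps)
    if kind == "ramp":
        span = rng.uniform(*cfg.ramp_minutes)
        t_hi = rng.uniform(lo + 0.5 * (hi - lo), hi)
        return TemperatureProfile(
            np.array([0.0, span]), np.array([lo, t_hi]), interpolation="linear"
        )
    # sinusoid around the band centre, amplitude within the bounds
    mean = 0.5 * (lo + hi)
    amp = rng.uniform(0.25, 0.5) * (hi - lo)
    span = 2.0 * cfg.sinusoid_period
    ts = np.arange(0.0, span + cfg.sinusoid_resolution, cfg.sinusoid_resolution)
    temps = mean + amp * np.sin(2 * math.pi * ts / cfg.sinusoid_period)
    return TemperatureProfile(ts, temps, interpolation="linear")


def sample_under_profile(
    profile: TemperatureProfile,
    model: LogLogisticTDTModel,
    n: int,
    seed,
    grid_step: float = 0.1,
    horizon_multiplier: float = 10.0,
    max_extensions: int = 6,
) -> np.ndarray:
    """Inverse-CDF draws of failure times under a profile.

    Uniform survival levels u are mapped through the increasing-variance
    prediction's survival curve; if any u falls below the survival still
    remaining at the horizon, the horizon is doubled (up to
    ``max_extensions`` times, with a warning) and those draws resampled
    from the longer curve.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=int(n))
    mult = horizon_multiplier
    for attempt in range(max_extensions + 1):
        pred = predict_survival_increasing_variance(
            profile, model, grid_step=grid_step, horizon_multiplier=mult
        )
        s_floor = float(pred.survival[-1])
        if np.all(u > s_floor):
            break
        mult *= 2.0
        if attempt == max_extensions:
            raise RuntimeError(
                f"survival floor {s_floor:.3g} above smallest draw after "
                f"{max_extensions} horizon extensions"
            )
        warnings.warn(
            f"extending sampling horizon to {mult:.0f}x (survival at horizon "
            f"{s_floor:.3g})",
            stacklevel=2,
        )
    # invert the nonincreasing grid curve: S(t)=u  <=>  t = interp on -S
    s = pred.survival
    t = pred.times
    order = np.argsort(-s, kind="stable")  # S decreasing along t already
    s_desc, t_asc = s[order], t[order]
    times = np.interp(-u, -s_desc, t_asc)
    return times


def generate_fluctuating_sets(
    cfg: SimulationConfig,
    model: LogLogisticTDTModel | None = None,
    sexes: Sequence[str] | None = None,
) -> list[SetObservation]:
    """n_sets assay sets with profiles from
    :func:`generate_temperature_profile` and failure times drawn from
    the (true) increasing-variance model."""
    model = model or cfg.model
    sets = []
    for i in range(cfg.n_sets):
        profile = generate_temperature_profile(cfg, i)
        draw_seed = np.random.SeedSequence([int(cfg.seed), 3, i])
        times = sample_under_profile(profile, model, cfg.n_per_set, draw_seed)
        sets.append(
            SetObservation(
                set_id=f"set{i:02d}",
                profile=profile,
                observed_times=times,
                sex=None if sexes is None else sexes[i % len(sexes)],
            )
        )
    return sets
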