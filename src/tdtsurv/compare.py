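"""Scoring the three fluctuating-temperature predictors against
observed failure times.

For each assay set (one temperature profile plus the failure times of
the individuals exposed to it) the three models predict a median failure
time; the two probabilistic models additionally predict the full failure
density, scored by log-likelihood.  Summaries follow the conventions of
the field: per-model sum of absolute median errors (SAE), per-set
log-likelihood difference Delta-LL = increasing_variance - rezende
(positive favours the increasing-variance model), a one-sample paired t
test on the Delta-LL values, and the count of sets favouring each model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fluctuating import (
    LogLogisticTDTModel,
    TemperatureProfile,
    build_average_relative_curve,
    predict_median_jorgensen,
    predict_survival_increasing_variance,
    predict_survival_rezende,
    profile_log_likelihood,
)
from .static_fit import (
    FailureDataset,
    fit_aft_model,
    fit_cells,
    fit_tdt_regression,
    test_shape_trend,
)

__all__ = [
    "SetObservation",
    "ComparisonConfig",
    "ModelComparisonTable",
    "SAEResult",
    "PairedTestResult",
    "DegenerateVarianceError",
    "sum_absolute_error",
    "paired_delta_loglik_test",
    "run_full_comparison",
]

MODELS = ("jorgensen", "rezende", "increasing_variance")


class DegenerateVarianceError(ValueError):
    """Paired test undefined: the differences have zero variance."""


@dataclass
class SetObservation:
    """One fluctuating-temperature assay set: the profile the chamber
    ran and the observed failure times of its individuals."""

    set_id: str
    profile: TemperatureProfile
    observed_times: np.ndarray
    sex: str | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed_times, dtype=float)
        if obs.size == 0:
            raise ValueError(f"set {self.set_id}: no observed times")
        if np.any(obs <= 0):
            raise ValueError(f"set {self.set_id}: nonpositive observed time")
        self.observed_times = obs

    @property
    def observed_median(self) -> float:
        """Midpoint sample median of the observed failure times."""
        return float(np.median(self.observed_times))


@dataclass
class SAEResult:
    total: float
    per_set: dict[str, float]


def sum_absolute_error(
    predictions: Mapping[str, float], observations: Mapping[str, float]
) -> SAEResult:
    """Sum over sets of |predicted median - observed median| (minutes)."""
    missing = set(predictions) ^ set(observations)
    if missing:
        raise KeyError(f"prediction/observation key mismatch: {sorted(missing)}")
    per_set = {k: abs(predictions[k] - observations[k]) for k in predictions}
    return SAEResult(total=float(sum(per_set.values())), per_set=per_set)


@dataclass
class PairedTestResult:
    t_statistic: float
    df: int
    p_value: float
    n_positive: int
    n: int


def paired_delta_loglik_test(deltas: Sequence[float]) -> PairedTestResult:
    """One-sample t test of mean(Delta-LL) = 0 with df = n - 1 and a
    two-sided p value; ties (Delta = 0) count as non-positive."""
    d = np.asarray(deltas, dtype=float)
    if len(d) < 2:
        raise ValueError("need >= 2 paired differences")
    if float(np.std(d, ddof=1)) == 0.0:
        raise DegenerateVarianceError(
            "all paired differences are identical; t statistic undefined"
        )
    res = stats.ttest_1samp(d, 0.0)
    return PairedTestResult(
        t_statistic=float(res.statistic),
        df=len(d) - 1,
        p_value=float(res.pvalue),
        n_positive=int(np.sum(d > 0)),
        n=len(d),
    )


@dataclass
class ComparisonConfig:
    """Knobs for the end-to-end comparison.

    ``shape_link='auto'`` uses the temperature-linked shape only when the
    shape-trend LR test rejects at ``trend_alpha`` (otherwise constant
    shape), mirroring the decide-then-predict workflow.  ``tdt_source``
    picks whether the TDT line is regressed on fitted per-cell scales or
    raw sample medians.
    """

    shape_link: str = "auto"  # constant | log-linear | auto
    trend_alpha: float = 0.05
    tdt_source: str = "cell_scale"  # cell_scale | sample_median
    grid_step: float = 0.1
    horizon_multiplier: float = 10.0
    density_floor: float = 1e-12
    bandwidth: float | str = "silverman"
    pool_sexes: bool = True
    shape_mode: str = "instantaneous"


@dataclass
class ModelComparisonTable:
    """Per-(set, model) predictions and the cross-set summaries."""

    rows: pd.DataFrame  # set_id, sex, model, predicted_median, observed_median, absolute_error, loglik
    sae: pd.DataFrame  # model [, sex] -> sum of absolute errors
    delta_ll: pd.DataFrame  # set_id, sex, delta_ll (increasing_variance - rezende)
    t_statistic: float
    df: int
    p_value: float
    n_positive: int
    n_sets: int
    config: ComparisonConfig = field(default_factory=ComparisonConfig)
    tdt: object = None
    model: LogLogisticTDTModel | None = None

    def summary_text(self) -> str:
        lines = ["model comparison summary", "-" * 40]
        for _, row in self.sae.iterrows():
            tag = f" ({row['sex']})" if "sex" in row and pd.notna(row["sex"]) else ""
            lines.append(f"SAE {row['model']}{tag}: {row['sae']:.1f} min")
        lines.append(
            f"paired t on Delta-LL: t={self.t_statistic:.4f}, df={self.df}, "
            f"p={self.p_value:.4g}"
        )
        lines.append(
            f"increasing variance better in {self.n_positive} of {self.n_sets} sets"
        )
        return "\n".join(lines)


def _fit_static_models(static_data: FailureDataset, config: ComparisonConfig):
    cells = fit_cells(static_data)
    if config.tdt_source == "cell_scale":
        tdt = fit_tdt_regression(cells)
    elif config.tdt_source == "sample_median":
        temps, meds = zip(
            *[
                (temp, float(np.median(g["time_min"])))
                for (_, temp), g in static_data.cells()
            ]
        )
        tdt = fit_tdt_regression(np.array(temps), np.array(meds))
    else:
        raise ValueError(f"unknown tdt_source {config.tdt_source!r}")

    link = config.shape_link
    if link == "auto":
        trend = test_shape_trend(static_data, pooling="pooled"
                                 if len(static_data.species) > 1 else "per-species")
        if isinstance(trend, dict):
            trend = next(iter(trend.values()))
        link = "log-linear" if trend.p_value < config.trend_alpha else "constant"
    aft = fit_aft_model(static_data, "loglogistic", shape_link=link)
    trange = (float(static_data.temperatures.min()), float(static_data.temperatures.max()))
    model = LogLogisticTDTModel.from_aft_fit(aft, fitted_range=trange)
    curve = build_average_relative_curve(static_data, tdt, bandwidth=config.bandwidth)
    return tdt, model, curve


def _predict_covering(predict, multiplier: float, max_obs: float,
                      max_doublings: int = 8):
    """Re-predict with a doubled horizon until the grid covers the
    longest observed failure time (heavy-tailed sets can outlive the
    default horizon)."""
    pred = predict(multiplier)
    for _ in range(max_doublings):
        if pred.times[-1] >= max_obs:
            return pred
        multiplier *= 2.0
        pred = predict(multiplier)
    raise RuntimeError(
        f"prediction horizon never reached the longest observation "
        f"({max_obs:.1f} min) after {max_doublings} doublings"
    )


def run_full_comparison(
    static_data: FailureDataset,
    sets: Sequence[SetObservation],
    config: ComparisonConfig | None = None,
) -> ModelComparisonTable:
    """Fit everything on the static data, predict every fluctuating set
    under the three models, and assemble the comparison table.

    Deterministic given its inputs.  When sets carry a sex label and
    ``pool_sexes`` is False, the static fits are computed per sex (the
    static data must then carry the same labels); SAE summaries are
    always broken out per sex when labels are present, while the paired
    Delta-LL test runs across all sets.
    """
    config = config or ComparisonConfig()
    if len(sets) == 0:
        raise ValueError("no assay sets supplied")
    sexes = {s.sex for s in sets}
    by_sex = not config.pool_sexes and sexes != {None}

    fits: dict[str | None, tuple] = {}
    if by_sex:
        for sex in sexes:
            sub = static_data.subset(static_data.frame["sex"] == sex)
            try:
                fits[sex] = _fit_static_models(sub, config)
            except Exception as exc:  # annotate the failing stage
                raise RuntimeError(f"static fits failed for sex={sex!r}: {exc}") from exc
    else:
        fits[None] = _fit_static_models(static_data, config)

    rows = []
    deltas = []
    for s in sets:
        tdt, model, curve = fits[s.sex if by_sex else None]
        max_obs = float(np.max(s.observed_times))
        try:
            jorg = predict_median_jorgensen(
                s.profile, tdt,
                horizon_multiplier=config.horizon_multiplier,
                grid_step=config.grid_step,
            )
            rez = _predict_covering(
                lambda m: predict_survival_rezende(
                    s.profile, curve, tdt,
                    grid_step=config.grid_step, horizon_multiplier=m,
                ),
                config.horizon_multiplier, max_obs,
            )
            inc = _predict_covering(
                lambda m: predict_survival_increasing_variance(
                    s.profile, model,
                    grid_step=config.grid_step, horizon_multiplier=m,
                    shape_mode=config.shape_mode,
                ),
                config.horizon_multiplier, max_obs,
            )
            ll_rez = profile_log_likelihood(rez, s.observed_times, config.density_floor)
            ll_inc = profile_log_likelihood(inc, s.observed_times, config.density_floor)
        except Exception as exc:
            raise RuntimeError(f"prediction failed for set {s.set_id!r}: {exc}") from exc
        obs_med = s.observed_median
        preds = {
            "jorgensen": (jorg.minutes, float("nan")),
            "rezende": (rez.median_tf, ll_rez.loglik),
            "increasing_variance": (inc.median_tf, ll_inc.loglik),
        }
        for name, (med, ll) in preds.items():
            rows.append(
                dict(set_id=s.set_id, sex=s.sex, model=name,
                     predicted_median=med, observed_median=obs_med,
                     absolute_error=abs(med - obs_med), loglik=ll)
            )
        deltas.append(dict(set_id=s.set_id, sex=s.sex,
                           delta_ll=ll_inc.loglik - ll_rez.loglik))

    rows_df = pd.DataFrame(rows)
    delta_df = pd.DataFrame(deltas)
    group_cols = ["model"] + (["sex"] if sexes != {None} else [])
    sae_df = (
        rows_df.groupby(group_cols, dropna=False)["absolute_error"]
        .sum()
        .rename("sae")
        .reset_index()
    )
    ttest = paired_delta_loglik_test(delta_df["delta_ll"].to_numpy())
    any_fit = next(iter(fits.values()))
    return ModelComparisonTable(
        rows=rows_df,
        sae=sae_df,
        delta_ll=delta_df,
        t_statistic=ttest.t_statistic,
        df=ttest.df,
        p_value=ttest.p_value,
        n_positive=ttest.n_positive,
        n_sets=ttest.n,
        config=config,
        tdt=any_fit[0],
        model=any_fit[1],
    )
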