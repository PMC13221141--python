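"""Damage accumulation and the three fluctuating-temperature predictors.

The binding consistency requirement is that every predictor collapses to
the static TDT answer at constant temperature; stepwise-profile cases
have closed-form oracles, and fine-grid brute force backs the
increasing-variance curve.
"""

import math

import numpy as np
import pytest

from tdtsurv.distributions import LogLogisticParams, survival_probability
from tdtsurv.fluctuating import (
    AverageRelativeCurve,
    LogLogisticTDTModel,
    TemperatureProfile,
    accumulate_damage,
    build_average_relative_curve,
    predict_median_jorgensen,
    predict_survival_increasing_variance,
    predict_survival_rezende,
    profile_log_likelihood,
)
from tdtsurv.static_fit import TDTRegression, fit_cells, fit_tdt_regression
from tdtsurv.synthetic import SimulationConfig, generate_static_dataset


def make_tdt(slope=-0.9, intercept=36.7):
    return TDTRegression(
        slope=slope, intercept=intercept, r_squared=1.0,
        residuals=np.zeros(2), temperatures=np.array([33.0, 40.0]),
    )


class StepTDT:
    """Oracle TDT with two fixed medians for closed-form damage sums."""

    def median_at(self, T):
        T = np.asarray(T, float)
        out = np.where(T < 38.0, 120.0, 60.0)
        return out if out.ndim else float(out)


class TestTemperatureProfile:
    def test_must_start_at_zero(self):
        with pytest.raises(ValueError):
            TemperatureProfile(np.array([5.0]), np.array([37.0]))

    def test_stepwise_lookup_and_hold(self):
        p = TemperatureProfile.stepwise([60.0, 30.0], [36.0, 39.0])
        assert p.temperature_at(0.0) == 36.0
        assert p.temperature_at(59.9) == 36.0
        assert p.temperature_at(60.0) == 39.0
        assert p.temperature_at(1e4) == 39.0  # held beyond last knot

    def test_linear_interpolation(self):
        p = TemperatureProfile(np.array([0.0, 100.0]), np.array([34.0, 42.0]),
                               interpolation="linear")
        assert p.temperature_at(50.0) == pytest.approx(38.0)


class TestAccumulateDamage:
    def test_constant_rate_is_linear(self):
        prof = TemperatureProfile.constant(37.0)
        traj = accumulate_damage(prof, lambda T: np.full_like(np.asarray(T, float), 0.01),
                                 t_end=250.0)
        assert traj.damage_at(250.0) == pytest.approx(2.5)
        assert traj.damage_at(0.0) == 0.0

    def test_two_step_piecewise(self):
        prof = TemperatureProfile.stepwise([60.0, 60.0], [36.0, 39.0])

        def rate(T):
            T = np.asarray(T, float)
            return np.where(T < 38.0, 1.0 / 120.0, 1.0 / 60.0)

        traj = accumulate_damage(prof, rate, t_end=120.0)
        assert traj.damage_at(60.0) == pytest.approx(0.5)
        assert traj.damage_at(90.0) == pytest.approx(1.0)

    def test_segment_permutation_preserves_total(self):
        durations = [30.0, 45.0, 25.0]
        temps = [35.0, 38.0, 41.0]
        rate = lambda T: 1.0 / np.exp(36.7 - 0.9 * np.asarray(T, float))
        total = None
        for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            prof = TemperatureProfile.stepwise(
                [durations[i] for i in order], [temps[i] for i in order]
            )
            d = accumulate_damage(prof, rate, t_end=100.0).damage_at(100.0)
            if total is None:
                total = d
            assert d == pytest.approx(total, rel=1e-12)

    def test_stepwise_closed_form_equals_trapezoid(self):
        # piecewise-constant rates: the trapezoid rule is exact at any grid
        prof = TemperatureProfile.stepwise([40.0, 40.0], [36.0, 39.0])
        rate = lambda T: 1.0 / np.exp(36.7 - 0.9 * np.asarray(T, float))
        exact = accumulate_damage(prof, rate, t_end=80.0)
        lin = TemperatureProfile(prof.times, prof.temperatures, "linear")
        # degenerate: both knots inside each segment see a constant rate,
        # compare at the segment midpoints computed by hand
        assert exact.damage_at(40.0) == pytest.approx(40.0 * float(rate(36.0)))
        assert exact.damage_at(80.0) == pytest.approx(
            40.0 * float(rate(36.0)) + 40.0 * float(rate(39.0))
        )

    def test_nonpositive_rate_names_segment(self):
        prof = TemperatureProfile.stepwise([60.0, 60.0], [36.0, 39.0])
        with pytest.raises(ValueError, match="segment"):
            accumulate_damage(prof, lambda T: np.where(
                np.asarray(T, float) > 38, -1.0, 0.01), t_end=120.0)


class TestJorgensen:
    def test_constant_temperature_reduces_to_t50(self):
        tdt = make_tdt()
        for T in (34.0, 37.0, 40.0):
            est = predict_median_jorgensen(TemperatureProfile.constant(T), tdt)
            assert est.minutes == pytest.approx(float(tdt.median_at(T)), abs=1e-9)

    def test_two_step_closed_form(self):
        prof = TemperatureProfile.stepwise([60.0, 240.0], [36.0, 39.0])
        est = predict_median_jorgensen(prof, StepTDT())
        assert est.minutes == pytest.approx(90.0, abs=1e-9)

    def test_time_reversal_when_median_on_boundary(self):
        # 60 min at t50=120 then 60 min at t50=120 at a hotter label:
        # reversing segments leaves the crossing time unchanged
        prof_a = TemperatureProfile.stepwise([90.0, 120.0], [36.0, 39.0])
        prof_b = TemperatureProfile.stepwise([120.0, 90.0], [39.0, 36.0])
        ma = predict_median_jorgensen(prof_a, StepTDT()).minutes
        mb = predict_median_jorgensen(prof_b, StepTDT()).minutes
        # damage at 210 min is identical (additivity); both cross 1 before
        da = 90.0 / 120.0 + 120.0 / 60.0
        assert da > 1
        # medians differ in timing but total-damage additivity holds:
        ta = accumulate_damage(prof_a, lambda T: 1.0 / StepTDT().median_at(T),
                               t_end=210.0).damage_at(210.0)
        tb = accumulate_damage(prof_b, lambda T: 1.0 / StepTDT().median_at(T),
                               t_end=210.0).damage_at(210.0)
        assert ta == pytest.approx(tb, rel=1e-12)
        assert ma > 0 and mb > 0

    def test_beyond_horizon_flagged(self):
        tdt = make_tdt()
        prof = TemperatureProfile.constant(34.0)
        est = predict_median_jorgensen(prof, tdt, horizon_multiplier=0.5)
        assert est.beyond_horizon
        assert math.isnan(est.minutes)


class TestAverageRelativeCurve:
    def test_degenerate_pool_drops_at_one(self):
        curve = AverageRelativeCurve(np.ones(50))
        assert curve.evaluate(0.999) == 1.0
        assert curve.evaluate(1.0) == 0.0
        assert curve.evaluate(2.0) == 0.0

    def test_empirical_survival_step_values(self):
        curve = AverageRelativeCurve([0.5, 1.0, 2.0])
        assert curve.empirical_survival(1.0 + 1e-12) == pytest.approx(1.0 / 3.0)
        assert curve.empirical_survival(0.4) == 1.0
        assert curve.empirical_survival(3.0) == 0.0

    def test_midpoint_curve_is_nonincreasing_from_one(self):
        rng = np.random.default_rng(5)
        curve = AverageRelativeCurve(rng.lognormal(0, 0.5, 200))
        r = np.linspace(0, 5, 500)
        s = curve.evaluate(r)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)

    def test_matches_true_curve_on_constant_shape_data(self):
        # pooled relative times from a constant-shape log-logistic have
        # survival S(r) = (1 + r^k)^(-1)
        cfg = SimulationConfig(seed=19, n_per_cell=250,
                               gamma0=float(np.log(3.0)), gamma1=0.0)
        sim = generate_static_dataset(cfg)  # 8 cells x 250 = 2000
        tdt = fit_tdt_regression(fit_cells(sim.dataset))
        curve = build_average_relative_curve(sim.dataset, tdt)
        r = np.geomspace(0.05, 5.0, 200)
        true_s = 1.0 / (1.0 + r**3.0)
        assert np.max(np.abs(curve.evaluate(r) - true_s)) < 0.05

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            AverageRelativeCurve([])


class TestRezendePredictor:
    def test_constant_temperature_stretches_curve(self):
        rng = np.random.default_rng(11)
        curve = AverageRelativeCurve(rng.lognormal(0, 0.4, 500))
        tdt = make_tdt()
        T = 37.0
        pred = predict_survival_rezende(TemperatureProfile.constant(T), curve, tdt)
        t50 = float(tdt.median_at(T))
        np.testing.assert_allclose(
            pred.survival, curve.evaluate(pred.times / t50), atol=1e-9
        )

    def test_degenerate_curve_matches_jorgensen(self):
        curve = AverageRelativeCurve(np.ones(30))
        prof = TemperatureProfile.stepwise([60.0, 240.0], [36.0, 39.0])
        tdt = StepTDT()
        rez = predict_survival_rezende(prof, curve, tdt)
        jorg = predict_median_jorgensen(prof, tdt)
        assert rez.median_tf == pytest.approx(jorg.minutes, abs=1e-3)

    def test_survival_nonincreasing(self):
        rng = np.random.default_rng(13)
        curve = AverageRelativeCurve(rng.lognormal(0, 0.6, 300))
        prof = TemperatureProfile.stepwise([30.0, 60.0, 30.0], [39.0, 35.0, 41.0])
        pred = predict_survival_rezende(prof, curve, make_tdt())
        assert pred.survival[0] == 1.0
        assert np.all(np.diff(pred.survival) <= 1e-12)


class TestIncreasingVariancePredictor:
    def test_constant_temperature_exact_reduction(self, default_model):
        for T in (34.0, 37.0, 40.0):
            pred = predict_survival_increasing_variance(
                TemperatureProfile.constant(T), default_model
            )
            p = LogLogisticParams(default_model.scale_at(T), default_model.shape_at(T))
            assert np.max(np.abs(pred.survival - survival_probability(pred.times, p))) < 1e-9
            assert pred.median_tf == pytest.approx(p.scale, abs=1e-4)

    def test_constant_shape_stepwise_matches_fine_grid_oracle(self):
        model = LogLogisticTDTModel(beta0=36.7, beta1=-0.9,
                                    gamma0=math.log(3.0), gamma1=0.0)
        prof = TemperatureProfile.stepwise([20.0, 30.0, 40.0], [39.0, 36.0, 40.0])
        pred = predict_survival_increasing_variance(prof, model, grid_step=0.1)
        # brute-force oracle on a 1e-3-minute grid (knots included so the
        # trapezoid rule sees the rate jumps exactly)
        ts = np.union1d(np.arange(0.0, pred.times[-1] + 1e-3, 1e-3),
                        np.append(prof.times, pred.times[-1]))
        # midpoint rule: exact for a piecewise-constant rate once the
        # segment knots are grid points
        mids = 0.5 * (ts[1:] + ts[:-1])
        rates = 1.0 / model.scale_at(prof.temperature_at(mids))
        D = np.concatenate([[0.0], np.cumsum(rates * np.diff(ts))])
        S_oracle = 1.0 / (1.0 + np.maximum(D, 1e-300) ** 3.0)
        S_oracle[D <= 0] = 1.0
        on_grid = np.interp(pred.times, ts, S_oracle)
        assert np.max(np.abs(pred.survival - on_grid)) < 1e-6

    def test_grid_refinement_invariance(self, default_model):
        prof = TemperatureProfile.stepwise([45.0, 45.0], [36.0, 39.5])
        a = predict_survival_increasing_variance(prof, default_model, grid_step=0.1)
        b = predict_survival_increasing_variance(prof, default_model, grid_step=0.02)
        common = a.times[a.times <= min(a.times[-1], b.times[-1])]
        sa = np.interp(common, a.times, a.survival)
        sb = np.interp(common, b.times, b.survival)
        assert np.max(np.abs(sa - sb)) < 1e-4

    def test_survival_starts_at_one_and_nonincreasing(self, default_model):
        prof = TemperatureProfile.stepwise([30.0, 30.0, 30.0], [40.0, 35.0, 41.0])
        pred = predict_survival_increasing_variance(prof, default_model)
        assert pred.survival[0] == 1.0
        assert np.all(np.diff(pred.survival) <= 1e-12)

    def test_extrapolation_warns(self):
        model = LogLogisticTDTModel(36.7, -0.9, 7.2, -0.17, fitted_range=(33.0, 40.0))
        prof = TemperatureProfile.constant(42.0)
        with pytest.warns(UserWarning, match="beyond the fitted"):
            predict_survival_increasing_variance(prof, model)

    def test_nonfinite_model_rejected(self):
        model = LogLogisticTDTModel(math.nan, -0.9, 7.2, 0.0)
        with pytest.raises(ValueError):
            predict_survival_increasing_variance(
                TemperatureProfile.constant(37.0), model
            )


class TestProfileLogLikelihood:
    def test_observation_at_median_constant_temperature(self, default_model):
        T = 37.0
        pred = predict_survival_increasing_variance(
            TemperatureProfile.constant(T), default_model, grid_step=0.01
        )
        a = default_model.scale_at(T)
        k = default_model.shape_at(T)
        res = profile_log_likelihood(pred, [a])
        assert res.loglik == pytest.approx(math.log(k / (4 * a)), abs=5e-3)
        assert res.n_floored == 0

    def test_doubling_observations_doubles_loglik(self, default_model):
        pred = predict_survival_increasing_variance(
            TemperatureProfile.constant(37.0), default_model
        )
        obs = [10.0, 25.0, 40.0]
        one = profile_log_likelihood(pred, obs).loglik
        two = profile_log_likelihood(pred, obs + obs).loglik
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_observation_beyond_grid_instructs_longer_horizon(self, default_model):
        pred = predict_survival_increasing_variance(
            TemperatureProfile.constant(37.0), default_model
        )
        with pytest.raises(ValueError, match="horizon"):
            profile_log_likelihood(pred, [pred.times[-1] + 1.0])

    def test_floor_counts_reported(self, default_model):
        pred = predict_survival_increasing_variance(
            TemperatureProfile.constant(40.0), default_model
        )
        # the far tail of the grid has ~zero finite-difference density
        res = profile_log_likelihood(pred, [pred.times[-1]], floor=1e-6)
        assert res.n_floored >= 0
        assert np.isfinite(res.loglik)


class TestCrossModelConsistency:
    def test_all_three_medians_agree_at_constant_temperature(self):
        cfg = SimulationConfig(seed=23, n_per_cell=200)
        sim = generate_static_dataset(cfg)
        cells = fit_cells(sim.dataset)
        tdt = fit_tdt_regression(cells)
        curve = build_average_relative_curve(sim.dataset, tdt)
        from tdtsurv.static_fit import fit_aft_model

        aft = fit_aft_model(sim.dataset, "loglogistic", "log-linear")
        model = LogLogisticTDTModel.from_aft_fit(aft)
        T = 37.0
        prof = TemperatureProfile.constant(T)
        static_median = float(tdt.median_at(T))
        jorg = predict_median_jorgensen(prof, tdt).minutes
        rez = predict_survival_rezende(prof, curve, tdt).median_tf
        inc = predict_survival_increasing_variance(prof, model).median_tf
        assert jorg == pytest.approx(static_median, abs=1e-6)
        # the probabilistic medians carry sampling noise from their fits
        assert rez == pytest.approx(static_median, rel=0.05)
        assert inc == pytest.approx(static_median, rel=0.05)

    def test_rezende_and_increasing_variance_agree_for_constant_shape(self):
        # with a constant-shape generator the pooled curve estimates the
        # same log-logistic the parametric model fits
        cfg = SimulationConfig(seed=29, n_per_cell=625,
                               gamma0=float(np.log(3.0)), gamma1=0.0)
        sim = generate_static_dataset(cfg)  # 8 x 625 = 5000 records
        cells = fit_cells(sim.dataset)
        tdt = fit_tdt_regression(cells)
        curve = build_average_relative_curve(sim.dataset, tdt)
        from tdtsurv.static_fit import fit_aft_model

        model = LogLogisticTDTModel.from_aft_fit(
            fit_aft_model(sim.dataset, "loglogistic", "constant")
        )
        prof = TemperatureProfile.stepwise([40.0, 40.0], [36.0, 39.0])
        rez = predict_survival_rezende(prof, curve, tdt).median_tf
        inc = predict_survival_increasing_variance(prof, model).median_tf
        assert rez == pytest.approx(inc, rel=0.03)

    def test_inverse_sampling_recovers_median(self, default_model):
        from tdtsurv.synthetic import sample_under_profile

        prof = TemperatureProfile.stepwise([45.0, 60.0], [37.0, 39.0])
        pred = predict_survival_increasing_variance(prof, default_model)
        x = sample_under_profile(prof, default_model, 10**4, seed=31)
        # Monte-Carlo error of the sample median at n=1e4
        se = 1.0 / (2.0 * math.sqrt(10**4) * pred.density_at(pred.median_tf))
        assert np.median(x) == pytest.approx(pred.median_tf, abs=4 * se)
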