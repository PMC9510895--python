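import numpy as np
import pytest

from doxodyn.data_model import Condition, MultiDoseParams, TimeCourse, TreatmentSchedule
from doxodyn.dynamics import logistic_closed_form
from doxodyn.fitting import (
    FitSpec,
    _build_problem,
    apply_theta_dox_policy,
    fit_model,
    fit_untreated,
    least_squares_fit,
    param_confidence_intervals,
    prediction_intervals,
)
from doxodyn.synthetic_data import NoiseModel, generate_replicate

COND0 = Condition(1, 0.0, None, 1)

FAST = FitSpec(sim_rtol=1e-8, sim_atol=1e-2)


def untreated_tc(g0=0.025, theta=50000.0, n0=2000.0, horizon=600.0, cadence=4.0):
    t = np.arange(0.0, horizon, cadence)
    return TimeCourse(t, logistic_closed_form(n0, g0, theta, t), "u1", COND0)


class TestFitUntreated:
    def test_noiseless_recovery(self):
        tc = untreated_tc()
        fit = fit_untreated(tc)
        assert fit.param_value("g0") == pytest.approx(0.025, rel=1e-3)
        assert fit.param_value("theta_u") == pytest.approx(50000.0, rel=1e-3)
        assert fit.param_value("N0") == pytest.approx(2000.0, rel=1e-3)

    def test_constant_data_degenerate_solution(self):
        # constant data admit a solution manifold: g0 = 0 (no growth) or
        # N0 = theta_u (fixed point); the solver lands on one of the two
        t = np.arange(0.0, 100.0, 4.0)
        tc = TimeCourse(t, np.full(t.size, 3000.0), "flat", COND0)
        fit = fit_untreated(tc)
        g0 = fit.param_value("g0")
        at_fixed_point = fit.param_value("N0") == pytest.approx(
            fit.param_value("theta_u"), rel=1e-6
        )
        assert g0 <= 1e-6 or at_fixed_point
        assert fit.convergence["cost"] <= 1e-12  # perfect fit either way

    def test_noisy_recovery_median_within_10pct(self):
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(10):
            tc0 = untreated_tc()
            noisy = tc0.counts * rng.lognormal(0, 0.05, tc0.counts.size)
            fit = fit_untreated(TimeCourse(tc0.times, noisy, "n", COND0))
            errs.append(abs(fit.param_value("g0") - 0.025) / 0.025)
        assert np.median(errs) <= 0.10

    def test_too_few_points(self):
        t = np.arange(0.0, 20.0, 4.0)
        tc = TimeCourse(t, np.full(t.size, 100.0), "short", COND0)
        with pytest.raises(ValueError):
            fit_untreated(tc)


@pytest.fixture(scope="module")
def single_dose_fit():
    params = MultiDoseParams(
        g0=0.025, gs=0.015, gd=0.018, kd=-0.035,
        theta_u=53873.0, theta_dox=42000.0,
        fs=[0.3], gamma_d=[0.04], N0=2000.0, mode="constant",
    )
    sched = TreatmentSchedule([48.0], [75.0])
    tc, _ = generate_replicate(
        params, sched, cadence_h=4.0, horizon_h=800.0,
        noise=NoiseModel(multiplicative_cv=0.0), rng=0,
    )
    fit = fit_model(tc, sched, "constant", FAST, theta_u=53873.0)
    return params, sched, tc, fit


class TestFitModel:
    def test_noiseless_recovery_within_1pct(self, single_dose_fit):
        params, _, _, fit = single_dose_fit
        true = {
            "g0": params.g0, "gs": params.gs, "gd": params.gd, "kd": params.kd,
            "fs": params.fs[0], "gamma_d": params.gamma_d[0],
            "N0": params.N0, "theta_dox": params.theta_dox,
        }
        for name, val in true.items():
            assert fit.param_value(name) == pytest.approx(val, rel=1e-2), name

    def test_fs_one_fit_quality(self):
        params = MultiDoseParams(
            g0=0.025, gs=0.015, gd=0.018, kd=-0.035,
            theta_u=53873.0, theta_dox=42000.0,
            fs=[1.0], gamma_d=[0.04], N0=2000.0, mode="constant",
        )
        sched = TreatmentSchedule([48.0], [75.0])
        tc, _ = generate_replicate(
            params, sched, cadence_h=4.0, horizon_h=600.0,
            noise=NoiseModel(0.0), rng=0,
        )
        fit = fit_model(tc, sched, "constant", FAST, theta_u=53873.0)
        assert fit.gof["nrmse"] < 1.0

    def test_stationarity_on_refit(self, single_dose_fit):
        _, sched, tc, fit = single_dose_fit
        spec2 = FitSpec(
            init=dict(zip(fit.free_names, fit.estimates)),
            sim_rtol=1e-8, sim_atol=1e-2,
        )
        refit = fit_model(tc, sched, "constant", spec2, theta_u=53873.0)
        c0, c1 = fit.convergence["cost"], refit.convergence["cost"]
        assert c1 <= c0 * (1 + 1e-8) + 1e-12

    def test_adaptive_on_constant_generated_data_consistent(self):
        params = MultiDoseParams(
            g0=0.025, gs=0.015, gd=0.018, kd=-0.035,
            theta_u=53873.0, theta_dox=42000.0,
            fs=[0.3, 0.3], gamma_d=[0.04, 0.04], N0=2000.0, mode="constant",
        )
        sched = TreatmentSchedule([48.0, 288.0], [75.0, 75.0])
        tc, _ = generate_replicate(
            params, sched, cadence_h=4.0, horizon_h=800.0,
            noise=NoiseModel(multiplicative_cv=0.01), rng=3,
        )
        fit = fit_model(tc, sched, "adaptive", FAST, theta_u=53873.0)
        fs1, fs2 = fit.param_value("fs_1"), fit.param_value("fs_2")
        lo1, hi1 = fit.param_ci["fs_1"]
        lo2, hi2 = fit.param_ci["fs_2"]
        assert max(lo1, lo2) <= min(hi1, hi2)  # CIs overlap
        assert fs1 == pytest.approx(fs2, abs=0.1)

    def test_objective_never_above_initial_guess(self, single_dose_fit):
        _, sched, tc, fit = single_dose_fit
        from doxodyn.fitting import _build_problem

        problem = _build_problem(fit.free_names, FAST, 53873.0, float(tc.counts[0]))
        r0 = fit.model_fn(problem.x0, tc.times) - tc.counts
        assert fit.convergence["cost"] <= 0.5 * float(r0 @ r0) + 1e-12

    def test_estimates_respect_bounds(self, single_dose_fit):
        _, _, _, fit = single_dose_fit
        for name, est in zip(fit.free_names, fit.estimates):
            lo, hi = fit.bounds[name]
            assert lo <= est <= hi

    def test_requires_pre_and_post_treatment_span(self):
        sched = TreatmentSchedule([48.0], [75.0])
        t = np.arange(60.0, 200.0, 4.0)
        tc = TimeCourse(t, np.full(t.size, 1000.0), "late", Condition(1, 75.0, None, 1))
        with pytest.raises(ValueError):
            fit_model(tc, sched, "constant", FAST)


class TestThetaDoxPolicy:
    def _fits(self, fs_values, horizon=700.0):
        sched = TreatmentSchedule([48.0], [75.0])
        fits = []
        for i, fs in enumerate(fs_values):
            params = MultiDoseParams(
                g0=0.025, gs=0.015, gd=0.018, kd=-0.035,
                theta_u=53873.0, theta_dox=42000.0,
                fs=[fs], gamma_d=[0.04], N0=2000.0, mode="constant",
            )
            tc, _ = generate_replicate(
                params, sched, cadence_h=6.0, horizon_h=horizon,
                noise=NoiseModel(0.0), rng=i,
                condition=Condition(1, 75.0, None, 1), replicate_id=f"r{i}",
            )
            fits.append(fit_model(tc, sched, "constant", FAST, theta_u=53873.0))
        return fits

    def test_all_above_threshold_identity(self):
        fits = self._fits([0.4, 0.5])
        out = apply_theta_dox_policy(fits, theta_u=53873.0, threshold=0.30)
        assert [f.param_value("theta_dox") for f in out] == [
            f.param_value("theta_dox") for f in fits
        ]

    def test_below_threshold_refit_with_mean(self):
        # low-fs replicate never regrows; three high-fs replicates identify theta
        fits = self._fits([0.45, 0.5, 0.55]) + self._fits([0.02], horizon=300.0)
        last = fits[-1].last_observed_count
        assert last <= 0.30 * 53873.0
        out = apply_theta_dox_policy(fits, theta_u=53873.0, threshold=0.30)
        frees = [f for f in out if "theta_dox" in f.free_names]
        fixed = [f for f in out if "theta_dox" in f.fixed_params]
        assert len(frees) == 3 and len(fixed) == 1
        expected = np.mean([f.param_value("theta_dox") for f in frees])
        assert fixed[0].fixed_params["theta_dox"] == pytest.approx(expected)

    def test_zero_threshold_all_free(self):
        fits = self._fits([0.4, 0.02])
        out = apply_theta_dox_policy(fits, theta_u=53873.0, threshold=0.0)
        assert all("theta_dox" in f.free_names for f in out)

    def test_empty_pass1_errors(self):
        fits = self._fits([0.02], horizon=300.0)
        with pytest.raises(ValueError, match="theta_dox"):
            apply_theta_dox_policy(fits, theta_u=53873.0, threshold=0.99)


class TestConfidenceMachinery:
    """Linear/closed-form oracles for the generic CI and band machinery."""

    @staticmethod
    def _linear_fit(seed=0, n=30):
        rng = np.random.default_rng(seed)
        t = np.linspace(0.0, 10.0, n)
        y = 2.0 + 0.7 * t + rng.normal(0, 0.4, n)

        def model_fn(x, tt):
            return x[0] + x[1] * tt

        from doxodyn.fitting import _Problem, _make_result

        prob = _Problem(
            ["a", "b"], np.array([0.0, 0.0]),
            np.array([-np.inf, -np.inf]), np.array([np.inf, np.inf]),
        )
        spec = FitSpec()
        res = least_squares_fit(model_fn, t, y, prob, spec)
        fit = _make_result(res, prob, model_fn, t, y, None, {}, None, None, spec)
        return t, y, model_fn, fit

    def test_matches_ols_closed_form(self):
        import statsmodels.api as sm

        t, y, _, fit = self._linear_fit()
        X = sm.add_constant(t)
        ols = sm.OLS(y, X).fit()
        ci, _ = param_confidence_intervals(fit)
        sm_ci = ols.conf_int(alpha=0.05)
        assert fit.estimates == pytest.approx(ols.params, rel=1e-6)
        assert ci["a"] == pytest.approx(tuple(sm_ci[0]), rel=1e-6)
        assert ci["b"] == pytest.approx(tuple(sm_ci[1]), rel=1e-6)

    def test_prediction_band_matches_textbook_formula(self):
        t, y, _, fit = self._linear_fit(seed=1)
        grid = np.linspace(0.0, 10.0, 11)
        lo, mid, hi = prediction_intervals(fit, grid)
        # textbook mean-response band for simple linear regression
        from scipy import stats as sps

        n = len(t)
        a, b = fit.estimates
        resid = y - (a + b * t)
        s2 = resid @ resid / (n - 2)
        tbar = t.mean()
        sxx = np.sum((t - tbar) ** 2)
        half = sps.t.ppf(0.975, n - 2) * np.sqrt(
            s2 * (1.0 / n + (grid - tbar) ** 2 / sxx)
        )
        np.testing.assert_allclose(hi - mid, half, rtol=1e-5)
        np.testing.assert_allclose(mid - lo, half, rtol=1e-5)

    def test_zero_residual_fit_zero_width(self):
        t = np.linspace(0.0, 10.0, 20)
        y = 1.5 + 0.3 * t

        def model_fn(x, tt):
            return x[0] + x[1] * tt

        from doxodyn.fitting import _Problem, _make_result

        prob = _Problem(
            ["a", "b"], np.array([0.0, 0.0]),
            np.array([-np.inf, -np.inf]), np.array([np.inf, np.inf]),
        )
        spec = FitSpec()
        res = least_squares_fit(model_fn, t, y, prob, spec)
        fit = _make_result(res, prob, model_fn, t, y, None, {}, None, None, spec)
        for lo, hi in fit.param_ci.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-6)
        lo, mid, hi = prediction_intervals(fit, t)
        assert np.max(hi - lo) == pytest.approx(0.0, abs=1e-5)
        assert np.all(lo <= mid + 1e-12) and np.all(mid <= hi + 1e-12)

    def test_unidentified_parameter_flagged(self):
        t = np.linspace(0.0, 10.0, 15)
        y = 2.0 * t

        def model_fn(x, tt):
            return x[0] * tt + 0.0 * x[1]  # second parameter has no effect

        from doxodyn.fitting import _Problem, _make_result

        prob = _Problem(
            ["slope", "ghost"], np.array([1.0, 0.5]),
            np.array([-np.inf, -np.inf]), np.array([np.inf, np.inf]),
        )
        spec = FitSpec()
        res = least_squares_fit(model_fn, t, y, prob, spec)
        fit = _make_result(res, prob, model_fn, t, y, None, {}, None, None, spec)
        assert fit.ci_flags.get("ghost") == "unidentified"

    def test_ci_coverage_monte_carlo(self):
        # 200 refits of the closed-form untreated model at 5% noise
        rng = np.random.default_rng(2024)
        t = np.arange(0.0, 600.0, 6.0)
        truth = logistic_closed_form(2000.0, 0.025, 50000.0, t)
        hits = 0
        n_trials = 200
        for _ in range(n_trials):
            noisy = truth * rng.lognormal(0, 0.05, truth.size)
            fit = fit_untreated(TimeCourse(t, noisy, "c", COND0))
            lo, hi = fit.param_ci["g0"]
            hits += lo <= 0.025 <= hi
        assert 0.88 * n_trials <= hits <= 0.99 * n_trials
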