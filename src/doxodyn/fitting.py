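"""Bounded nonlinear least-squares calibration of the growth models.

Mirrors the original calibration protocol: a trust-region reflective
least-squares solver with function, step, and optimality tolerances of 1e-6
and a cap of 20,000 function evaluations and iterations; the ODEs are solved
with an adaptive Runge-Kutta 4(5) scheme. Confidence intervals are asymptotic
(t-quantile times standard errors from the residual Jacobian).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from . import dynamics
from .data_model import (
    FitResult,
    MultiDoseParams,
    TimeCourse,
    TreatmentSchedule,
    UntreatedParams,
)
from .gof_stats import gof_report

__all__ = [
    "FitSpec",
    "DEFAULT_THETA_U",
    "fit_untreated",
    "fit_model",
    "apply_theta_dox_policy",
    "param_confidence_intervals",
    "prediction_intervals",
    "least_squares_fit",
]

#: Untreated carrying capacity used when none is supplied (cells); the mean of
#: logistic fits to the untreated replicates of the concentration experiment.
DEFAULT_THETA_U = 53873.0


@dataclass
class FitSpec:
    """Optimizer configuration: bounds, initial guesses, fixed parameters.

    ``bounds`` and ``init`` override per-parameter defaults; ``fixed`` pins a
    parameter to a value (it is then excluded from the free vector).
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    init: dict[str, float] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    ftol: float = 1e-6
    xtol: float = 1e-6
    gtol: float = 1e-6
    max_nfev: int = 20_000
    sim_rtol: float = 1e-8
    sim_atol: float = 1e-2
    n_starts: int = 1
    seed: int | None = None
    relative_residuals: bool = False

    def __post_init__(self) -> None:
        for v in (self.ftol, self.xtol, self.gtol):
            if v <= 0:
                raise ValueError("tolerances must be > 0")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound for {name} has lo > hi")
            if name in self.init and not (lo <= self.init[name] <= hi):
                raise ValueError(f"initial guess for {name} outside bounds")


def _default_bounds_init(name: str, theta_u: float, first_count: float):
    base = name.split("_")[0] if name.startswith(("fs_", "gamma")) else name
    if name.startswith("fs"):
        return (0.0, 1.0), 0.3
    if name.startswith("gamma_d"):
        return (0.0, 1.0), 0.01
    if base in ("g0", "gs", "gd"):
        return (0.0, 0.1), 0.02
    if name == "kd":
        return (-0.5, 0.0), -0.01
    if name == "theta_dox":
        return (0.1 * theta_u, 3.0 * theta_u), theta_u
    if name == "theta_u":
        return (0.5 * first_count, 50.0 * theta_u), theta_u
    if name == "N0":
        return (0.5 * first_count, 2.0 * first_count), first_count
    raise KeyError(name)


@dataclass
class _Problem:
    names: list[str]
    x0: np.ndarray
    lb: np.ndarray
    ub: np.ndarray


def _build_problem(names: Sequence[str], spec: FitSpec, theta_u: float, first_count: float) -> _Problem:
    x0, lb, ub = [], [], []
    for name in names:
        (blo, bhi), ini = _default_bounds_init(name, theta_u, first_count)
        blo, bhi = spec.bounds.get(name, (blo, bhi))
        ini = spec.init.get(name, ini)
        ini = min(max(ini, blo), bhi)
        x0.append(ini)
        lb.append(blo)
        ub.append(bhi)
    return _Problem(list(names), np.array(x0), np.array(lb), np.array(ub))


def least_squares_fit(
    model_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    t: np.ndarray,
    obs: np.ndarray,
    problem: _Problem,
    spec: FitSpec,
):
    """Run the bounded trust-region solver, optionally from multiple starts."""

    def residual(x):
        pred = model_fn(x, t)
        r = pred - obs
        if spec.relative_residuals:
            r = r / np.maximum(obs, 1.0)
        return r

    starts = [problem.x0]
    if spec.n_starts > 1:
        rng = np.random.default_rng(spec.seed)
        width = problem.ub - problem.lb
        finite = np.isfinite(width)
        for _ in range(spec.n_starts - 1):
            x = problem.x0.copy()
            x[finite] = problem.lb[finite] + width[finite] * rng.random(finite.sum())
            starts.append(x)

    best = None
    for x0 in starts:
        res = least_squares(
            residual,
            x0,
            bounds=(problem.lb, problem.ub),
            method="trf",
            ftol=spec.ftol,
            xtol=spec.xtol,
            gtol=spec.gtol,
            max_nfev=spec.max_nfev,
            x_scale="jac",
        )
        if best is None or res.cost < best.cost:
            best = res
    return best


def _ci_from_jacobian(jac, residuals, estimates, names, bounds, level=0.95):
    """Asymptotic intervals estimate +/- t * se, se from (J^T J)^{-1} s^2."""
    n, p = len(residuals), len(estimates)
    dof = max(n - p, 1)
    s2 = float(residuals @ residuals) / dof
    jtj = jac.T @ jac
    ci: dict[str, tuple[float, float]] = {}
    flags: dict[str, str] = {}
    try:
        cov = np.linalg.inv(jtj) * s2
        singular = False
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * s2
        singular = True
    tq = stats.t.ppf(0.5 + level / 2.0, dof)
    diag = np.diag(cov)
    # unidentified directions: (near-)zero Jacobian columns or singular JtJ
    col_norm = np.linalg.norm(jac, axis=0)
    scale = max(np.max(col_norm), 1.0)
    for i, name in enumerate(names):
        if singular or diag[i] < 0 or not np.isfinite(diag[i]) or col_norm[i] <= 1e-12 * scale:
            ci[name] = (-np.inf, np.inf)
            flags[name] = "unidentified"
            continue
        half = tq * np.sqrt(diag[i])
        lo, hi = estimates[i] - half, estimates[i] + half
        blo, bhi = bounds.get(name, (-np.inf, np.inf))
        if lo < blo or hi > bhi:
            flags[name] = "exceeds-bounds"
        ci[name] = (float(lo), float(hi))
    return ci, flags, cov, dof, s2


def _make_result(res, problem, model_fn, t, obs, params, fixed, tc, schedule, spec):
    pred = model_fn(res.x, t)
    residuals = pred - obs
    ci, flags, cov, dof, s2 = _ci_from_jacobian(
        res.jac, residuals, res.x, problem.names,
        {n: (lo, hi) for n, lo, hi in zip(problem.names, problem.lb, problem.ub)},
    )
    try:
        gof = gof_report(obs, pred).as_dict()
    except ValueError:  # degenerate data (zero variance) leaves metrics undefined
        gof = {"nrmse": float("nan"), "r2": float("nan"), "pcc": float("nan"),
               "ccc": float("nan"), "n_points": len(obs)}
    fit = FitResult(
        params=params,
        free_names=list(problem.names),
        estimates=res.x.copy(),
        param_ci=ci,
        fixed_params=dict(fixed),
        residuals=residuals,
        gof=gof,
        convergence={
            "status": int(res.status),
            "success": bool(res.success),
            "nfev": int(res.nfev),
            "cost": float(res.cost),
            "optimality": float(res.optimality),
            "message": res.message,
        },
        bounds={n: (float(lo), float(hi)) for n, lo, hi in zip(problem.names, problem.lb, problem.ub)},
        ci_flags=flags,
        time_course=tc,
        schedule=schedule,
    )
    # retained for delta-method machinery; not serialized
    fit.jac = res.jac
    fit.cov = cov
    fit.dof = dof
    fit.model_fn = model_fn
    fit.fit_spec = spec
    return fit


# ---------------------------------------------------------------------------
# Untreated logistic fit

def fit_untreated(tc: TimeCourse, spec: FitSpec | None = None) -> FitResult:
    """Fit the untreated logistic model (g0, theta_u, N0) to one replicate."""
    spec = spec or FitSpec()
    if len(tc) < 6:
        raise ValueError(f"replicate {tc.replicate_id}: need >= 6 points to fit")
    t = tc.times - tc.times[0]
    obs = tc.counts
    first = float(obs[0])
    theta_guess = max(float(obs.max()), first)
    names = [n for n in ("g0", "theta_u", "N0") if n not in spec.fixed]
    spec_local = dc_replace(
        spec,
        init={"theta_u": 1.5 * theta_guess, "N0": first, **spec.init},
        bounds={"theta_u": (0.5 * theta_guess, 50.0 * theta_guess), **spec.bounds},
    )
    problem = _build_problem(names, spec_local, theta_guess, first)

    def model_fn(x, tt):
        p = {**spec.fixed, **dict(zip(names, x))}
        return dynamics.logistic_closed_form(p["N0"], p["g0"], p["theta_u"], tt)

    res = least_squares_fit(model_fn, t, obs, problem, spec_local)
    p = {**spec.fixed, **dict(zip(names, res.x))}
    params = UntreatedParams(g0=p["g0"], theta_u=p["theta_u"], N0=p["N0"])
    return _make_result(res, problem, model_fn, t, obs, params, spec.fixed, tc, None, spec_local)


# ---------------------------------------------------------------------------
# Treated model fit

def _treated_names(n_doses: int, mode: str, theta_dox_free: bool, fixed: dict) -> list[str]:
    names = ["g0", "gs", "gd", "kd"]
    if mode == "constant" or n_doses == 1:
        names += ["fs", "gamma_d"]
    else:
        names += [f"fs_{i + 1}" for i in range(n_doses)]
        names += [f"gamma_d_{i + 1}" for i in range(n_doses)]
    names.append("N0")
    if theta_dox_free:
        names.append("theta_dox")
    return [n for n in names if n not in fixed]


def _params_from_vector(p: dict, n_doses: int, mode: str, theta_u: float) -> MultiDoseParams:
    if mode == "constant" or n_doses == 1:
        fs = [p["fs"]] * n_doses
        gd_list = [p["gamma_d"]] * n_doses
    else:
        fs = [p[f"fs_{i + 1}"] for i in range(n_doses)]
        gd_list = [p[f"gamma_d_{i + 1}"] for i in range(n_doses)]
    return MultiDoseParams(
        g0=p["g0"], gs=p["gs"], gd=p["gd"], kd=p["kd"],
        theta_u=theta_u, theta_dox=p["theta_dox"],
        fs=np.clip(fs, 0.0, 1.0), gamma_d=np.maximum(gd_list, 0.0),
        N0=p["N0"], mode=mode if n_doses > 1 else "constant",
    )


def fit_model(
    tc: TimeCourse,
    schedule: TreatmentSchedule,
    mode: str,
    spec: FitSpec | None = None,
    theta_u: float = DEFAULT_THETA_U,
    theta_dox_free: bool = True,
) -> FitResult:
    """Calibrate the treated model to one replicate time course.

    ``mode`` selects a single shared (fs, gamma_d) pair (``constant``) or one
    pair per dose (``adaptive``). ``theta_dox`` is fitted unless
    ``theta_dox_free`` is False or the spec fixes it; the two-pass fixing
    policy lives in :func:`apply_theta_dox_policy`.
    """
    spec = spec or FitSpec()
    if schedule.n_doses < 1:
        raise ValueError("treated fit requires at least one dose; use fit_untreated")
    if mode not in ("constant", "adaptive"):
        raise ValueError(f"unknown mode {mode!r}")
    if tc.times[0] >= schedule.dose_times[0] or tc.times[-1] <= schedule.dose_times[-1]:
        raise ValueError(
            f"replicate {tc.replicate_id}: time course must span pre- and post-treatment"
        )
    nd = schedule.n_doses
    first = float(tc.counts[0])
    names = _treated_names(nd, mode, theta_dox_free and "theta_dox" not in spec.fixed, spec.fixed)
    problem = _build_problem(names, spec, theta_u, first)
    fixed = dict(spec.fixed)
    if "theta_dox" not in names and "theta_dox" not in fixed:
        raise ValueError("theta_dox neither free nor fixed")

    penalty = 1e3 * float(np.max(tc.counts))

    def model_fn(x, tt):
        p = {**fixed, **dict(zip(names, x))}
        params = _params_from_vector(p, nd, mode, theta_u)
        try:
            traj = dynamics.simulate(
                params, schedule, tt, rtol=spec.sim_rtol, atol=spec.sim_atol
            )
        except dynamics.SimulationError:
            # absurd trial point (e.g. blow-up above capacity): penalize so
            # the trust region retreats instead of aborting the fit
            return np.full(np.asarray(tt).shape, penalty)
        return traj.N

    res = least_squares_fit(model_fn, tc.times, tc.counts, problem, spec)
    p = {**fixed, **dict(zip(names, res.x))}
    params = _params_from_vector(p, nd, mode, theta_u)
    return _make_result(res, problem, model_fn, tc.times, tc.counts, params, fixed, tc, schedule, spec)


def apply_theta_dox_policy(
    fits: list[FitResult],
    theta_u: float = DEFAULT_THETA_U,
    threshold: float = 0.30,
) -> list[FitResult]:
    """Two-pass treated-capacity fixing policy, grouped by experiment.

    Pass 1 keeps the free theta_dox estimate for replicates whose last
    observed count exceeds ``threshold * theta_u``. Pass 2 refits every other
    replicate with theta_dox fixed to the mean of the pass-1 estimates from
    the same experiment, since low final counts leave the treated capacity
    unidentifiable.
    """
    groups: dict[int, list[FitResult]] = {}
    for f in fits:
        if f.time_course is None or f.schedule is None:
            raise ValueError("fits must carry their source time course and schedule")
        groups.setdefault(f.time_course.condition.experiment_id, []).append(f)

    out: list[FitResult] = []
    for exp_id, group in sorted(groups.items()):
        pass1 = [f for f in group if f.last_observed_count > threshold * theta_u]
        rest = [f for f in group if f.last_observed_count <= threshold * theta_u]
        if rest and not pass1:
            raise ValueError(
                f"experiment {exp_id}: no replicate qualifies for a free theta_dox fit; "
                "supply theta_dox manually"
            )
        fixed_vals = []
        for f in pass1:
            if "theta_dox" in f.fixed_params:  # refit free
                spec = dc_replace(f.fit_spec, fixed={
                    k: v for k, v in f.fit_spec.fixed.items() if k != "theta_dox"
                })
                f = fit_model(
                    f.time_course, f.schedule, f.params.mode, spec, theta_u=theta_u
                )
            fixed_vals.append(f.param_value("theta_dox"))
            out.append(f)
        if rest:
            theta_fix = float(np.mean(fixed_vals))
            for f in rest:
                spec = dc_replace(
                    f.fit_spec, fixed={**f.fit_spec.fixed, "theta_dox": theta_fix}
                )
                out.append(
                    fit_model(
                        f.time_course, f.schedule, f.params.mode, spec,
                        theta_u=theta_u, theta_dox_free=False,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Confidence machinery

def param_confidence_intervals(fit: FitResult, level: float = 0.95):
    """Asymptotic per-parameter intervals from the solution Jacobian."""
    ci, flags, *_ = _ci_from_jacobian(
        fit.jac, fit.residuals, fit.estimates, fit.free_names, fit.bounds, level
    )
    return ci, flags


def prediction_intervals(
    fit: FitResult, t_grid, level: float = 0.95, rel_step: float = 1e-6
):
    """Delta-method 95% confidence band on the fitted curve N(t).

    Band half-width at each time is t_{dof} * sqrt(g^T cov g) with
    g = dN(t)/dparams by central finite differences at the estimate.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    x = fit.estimates
    center = fit.model_fn(x, t_grid)
    p = len(x)
    G = np.empty((t_grid.size, p))
    for i in range(p):
        h = rel_step * max(abs(x[i]), 1e-8)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        G[:, i] = (fit.model_fn(xp, t_grid) - fit.model_fn(xm, t_grid)) / (2 * h)
    var = np.einsum("ti,ij,tj->t", G, fit.cov, G)
    var = np.maximum(var, 0.0)
    tq = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    half = tq * np.sqrt(var)
    return center - half, center, center + half
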