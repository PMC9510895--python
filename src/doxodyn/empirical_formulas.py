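"""Concentration-dependent parameter formulas and uncertainty envelopes.

Each treated-model parameter gets a named functional form fitted to the
per-concentration medians of the single-dose calibrations: decaying
exponentials for the surviving fraction (with an additive offset) and the two
proliferation rates, a Morse-potential well for the asymptotic net rate of
damaged cells, and a flipped (saturating) exponential for the death-delay
rate. Uncertainty is propagated by Latin hypercube sampling of the formulas'
95% bands at a given concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import dynamics
from .data_model import MultiDoseParams, TreatmentSchedule
from .gof_stats import gof_report

__all__ = [
    "FORMS",
    "DEFAULT_FORM_BY_PARAM",
    "EmpiricalFormula",
    "eval_form",
    "eval_formula",
    "fit_formula",
    "lhs_sample",
    "simulate_band",
    "PARAM_ORDER",
]

PARAM_ORDER = ("fs", "gs", "gd", "kd", "gamma_d")


def _exp_decay(c, a):
    return a[0] * np.exp(-a[1] * c)


def _exp_decay_offset(c, a):
    return a[0] * np.exp(-a[1] * c) + a[2]


def _morse(c, a):
    return a[0] * (1.0 - np.exp(-a[1] * (c - a[2]))) ** 2 + a[3]


def _saturating_exp(c, a):
    return a[0] - a[1] * np.exp(-a[2] * c)


#: Form registry: name -> (function, n_coefficients). Extensible so exact
#: published parameterizations can be swapped in.
FORMS: dict[str, tuple] = {
    "exp_decay": (_exp_decay, 2),
    "exp_decay_offset": (_exp_decay_offset, 3),
    "morse": (_morse, 4),
    "saturating_exp": (_saturating_exp, 3),
}

DEFAULT_FORM_BY_PARAM = {
    "fs": "exp_decay_offset",
    "gs": "exp_decay",
    "gd": "exp_decay",
    "kd": "morse",
    "gamma_d": "saturating_exp",
}


def eval_form(form: str, coefficients, C) -> np.ndarray:
    if form not in FORMS:
        raise KeyError(f"unknown form {form!r}")
    fn, k = FORMS[form]
    a = np.asarray(coefficients, dtype=float)
    if a.size != k:
        raise ValueError(f"form {form!r} takes {k} coefficients, got {a.size}")
    return fn(np.asarray(C, dtype=float), a)


@dataclass
class EmpiricalFormula:
    """A fitted concentration->parameter relationship with its 95% machinery."""

    target_param: str
    form: str
    coefficients: np.ndarray
    coef_ci: dict[str, tuple[float, float]]
    cov: np.ndarray
    dof: int
    gof: dict[str, float] = field(default_factory=dict)
    concentrations: np.ndarray | None = None

    def __call__(self, C):
        return self.evaluate(C)

    def evaluate(self, C):
        val = eval_form(self.form, self.coefficients, C)
        if self.target_param == "fs":
            val = np.clip(val, 0.0, 1.0)
        return val

    def band(self, C, level: float = 0.95):
        """Delta-method (lower, point, upper) band at concentration(s) C."""
        C = np.atleast_1d(np.asarray(C, dtype=float))
        a = self.coefficients
        G = np.empty((C.size, a.size))
        for i in range(a.size):
            h = 1e-6 * max(abs(a[i]), 1e-8)
            ap, am = a.copy(), a.copy()
            ap[i] += h
            am[i] -= h
            G[:, i] = (eval_form(self.form, ap, C) - eval_form(self.form, am, C)) / (2 * h)
        var = np.maximum(np.einsum("ti,ij,tj->t", G, self.cov, G), 0.0)
        tq = stats.t.ppf(0.5 + level / 2.0, max(self.dof, 1))
        mid = eval_form(self.form, a, C)
        half = tq * np.sqrt(var)
        lo, hi = mid - half, mid + half
        if self.target_param == "fs":
            lo, mid, hi = (np.clip(v, 0.0, 1.0) for v in (lo, mid, hi))
        return lo, mid, hi

    def to_json_dict(self) -> dict:
        return {
            "target_param": self.target_param,
            "form": self.form,
            "coefficients": [float(v) for v in self.coefficients],
            "coef_ci": {k: [float(a), float(b)] for k, (a, b) in self.coef_ci.items()},
            "cov": np.asarray(self.cov).tolist(),
            "dof": int(self.dof),
            "gof": {k: float(v) for k, v in self.gof.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "EmpiricalFormula":
        return cls(
            target_param=d["target_param"],
            form=d["form"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            coef_ci={k: tuple(v) for k, v in d["coef_ci"].items()},
            cov=np.asarray(d["cov"], dtype=float),
            dof=int(d["dof"]),
            gof=dict(d.get("gof", {})),
        )


def eval_formula(f: EmpiricalFormula, C):
    return f.evaluate(C)


def _setup(form: str, c: np.ndarray, y: np.ndarray):
    """Data-driven initial guesses and generous non-binding bounds."""
    rng_y = max(float(y.max() - y.min()), 1e-9)
    amp = max(float(np.abs(y).max()), 1e-9)
    big = 1e3 * max(amp, rng_y)
    if form == "exp_decay":
        return [max(y[0], 1e-6), 0.01], ([0.0, 0.0], [big, 10.0])
    if form == "exp_decay_offset":
        return (
            [max(y[0] - y[-1], 1e-6), 0.01, y[-1]],
            ([0.0, 0.0, -big], [big, 10.0, big]),
        )
    if form == "morse":
        c_min = float(c[np.argmin(y)])
        return (
            [rng_y, 0.01, c_min, float(y.min())],
            ([0.0, 0.0, float(c.min()), float(y.min()) - 10 * rng_y],
             [big, 10.0, float(c.max()), float(y.max()) + 10 * rng_y]),
        )
    if form == "saturating_exp":
        return (
            [float(y[-1]), float(y[-1] - y[0]), 0.01],
            ([-big, -big, 0.0], [big, big, 10.0]),
        )
    raise KeyError(form)


def fit_formula(
    target: str,
    concentrations,
    medians,
    form: str | None = None,
    init=None,
    bounds=None,
    n_starts: int = 8,
    seed: int = 0,
) -> EmpiricalFormula:
    """Fit a named form to per-concentration parameter medians.

    Multi-start bounded least squares (the decay-rate coefficients make the
    problem mildly multimodal); coefficient CIs are asymptotic and the
    per-concentration band comes from the delta method.
    """
    form = form or DEFAULT_FORM_BY_PARAM[target]
    fn, k = FORMS[form]
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(medians, dtype=float)
    if c.size != y.size or c.size < k:
        raise ValueError(f"need at least {k} distinct concentrations for form {form!r}")
    if np.unique(c).size != c.size:
        raise ValueError("concentrations must be distinct")
    x0, (lb, ub) = _setup(form, c, y)
    if init is not None:
        x0 = list(init)
    if bounds is not None:
        lb, ub = bounds
    lb, ub = np.asarray(lb, float), np.asarray(ub, float)

    def residual(a):
        return fn(c, a) - y

    starts = [np.asarray(x0, float)]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts - 1):
        jitter = starts[0] * np.exp(rng.normal(0, 0.7, size=len(x0)))
        # decay-rate-like coefficients explore orders of magnitude
        starts.append(np.clip(jitter, lb, ub))
    best = None
    for s in starts:
        res = least_squares(
            residual, s, bounds=(lb, ub), method="trf",
            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=20_000,
        )
        if best is None or res.cost < best.cost:
            best = res

    r = residual(best.x)
    n, p = c.size, k
    dof = max(n - p, 1)
    s2 = float(r @ r) / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * s2
    tq = stats.t.ppf(0.975, dof)
    ci = {}
    for i in range(k):
        se = np.sqrt(max(cov[i, i], 0.0))
        ci[f"alpha_{i + 1}"] = (float(best.x[i] - tq * se), float(best.x[i] + tq * se))
    pred = fn(c, best.x)
    try:
        gof = gof_report(y, pred).as_dict()
    except ValueError:  # degenerate medians (zero variance)
        gof = {"nrmse": float("nan"), "r2": float("nan"), "pcc": float("nan"),
               "ccc": float("nan"), "n_points": n}
    return EmpiricalFormula(
        target_param=target, form=form, coefficients=best.x.copy(),
        coef_ci=ci, cov=cov, dof=dof, gof=gof, concentrations=c.copy(),
    )


def lhs_sample(
    formulas: dict[str, EmpiricalFormula], C: float, n: int, seed: int
) -> pd.DataFrame:
    """Latin hypercube over the five parameters' 95% bands at concentration C.

    Each dimension is uniform over its formula's band with exactly one sample
    per 1/n stratum; zero-width bands collapse to the midpoint. The surviving
    fraction is clamped to [0, 1]; rate parameters with sign constraints are
    clamped at zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    missing = [p for p in PARAM_ORDER if p not in formulas]
    if missing:
        raise ValueError(f"missing formulas for {missing}")
    lows, highs = [], []
    for p in PARAM_ORDER:
        lo, _, hi = formulas[p].band(C)
        lows.append(float(lo[0]))
        highs.append(float(hi[0]))
    lows, highs = np.array(lows), np.array(highs)
    sampler = qmc.LatinHypercube(d=len(PARAM_ORDER), seed=seed)
    unit = sampler.random(n)
    samples = lows + unit * (highs - lows)
    df = pd.DataFrame(samples, columns=list(PARAM_ORDER))
    df["fs"] = df["fs"].clip(0.0, 1.0)
    for p in ("gs", "gd", "gamma_d"):
        df[p] = df[p].clip(lower=0.0)
    return df


def simulate_band(
    combinations: pd.DataFrame,
    schedule: TreatmentSchedule,
    t_grid,
    theta_dox: float,
    g0: float,
    N0: float,
    theta_u: float,
    max_failure_frac: float = 0.05,
):
    """Forward-simulate every parameter combination; pointwise envelope.

    Returns a DataFrame with columns time, median, min, max. Failed
    simulations are skipped and logged; more than ``max_failure_frac``
    failures aborts.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    trajs, failures = [], []
    nd = schedule.n_doses
    for idx, row in combinations.iterrows():
        try:
            params = MultiDoseParams(
                g0=g0, gs=row["gs"], gd=row["gd"], kd=row["kd"],
                theta_u=theta_u, theta_dox=theta_dox,
                fs=[row["fs"]] * nd, gamma_d=[row["gamma_d"]] * nd,
                N0=N0, mode="constant",
            )
            trajs.append(dynamics.simulate(params, schedule, t_grid).N)
        except Exception as exc:  # noqa: BLE001 - logged and counted
            failures.append((idx, str(exc)))
    if len(failures) > max_failure_frac * len(combinations):
        raise RuntimeError(
            f"{len(failures)}/{len(combinations)} simulations failed: {failures[:3]}"
        )
    stack = np.vstack(trajs)
    return pd.DataFrame(
        {
            "time": t_grid,
            "median": np.median(stack, axis=0),
            "min": stack.min(axis=0),
            "max": stack.max(axis=0),
        }
    )
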