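"""Synthetic time-course generation with realistic measurement artifacts.

Generates ground-truth trajectories with the forward model, samples them on
an imaging cadence, and layers on multiplicative lognormal noise, sporadic
outlier spikes, and media-handling step discontinuities — the artifact
structure the preprocessing stage is built to undo. Every generated replicate
comes with a truth record sufficient to score parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dynamics
from .data_model import (
    Condition,
    DESIGN_TABLE,
    HOURS_PER_DAY,
    MultiDoseParams,
    TimeCourse,
    TreatmentSchedule,
    enumerate_design,
)
from .empirical_formulas import eval_form

__all__ = [
    "NoiseModel",
    "generate_replicate",
    "generate_experiment",
    "params_at_concentration",
    "DEFAULT_TRUE_COEFFS",
    "DEFAULT_SEED_DENSITY",
]

#: target seeding density (cells per well)
DEFAULT_SEED_DENSITY = 2000.0
DEFAULT_FIRST_DOSE_H = 48.0
DEFAULT_THETA_U = 53873.0

#: Generating concentration->parameter relationships (shape-faithful to the
#: published trends; magnitudes give doubling times of ~28 h untreated).
DEFAULT_TRUE_COEFFS: dict[str, tuple[str, list[float]]] = {
    "fs": ("exp_decay_offset", [0.85, 0.02, 0.05]),
    "gs": ("exp_decay", [0.025, 0.01]),
    "gd": ("exp_decay", [0.025, 0.008]),
    "kd": ("morse", [0.04, 0.01, 50.0, -0.045]),
    "gamma_d": ("saturating_exp", [0.06, 0.035, 0.02]),
}


@dataclass
class NoiseModel:
    """Measurement artifact configuration for one generated replicate."""

    multiplicative_cv: float = 0.05
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    discontinuities: list[tuple[float, float]] = field(default_factory=list)  # (time h, lost_fraction)

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0:
            raise ValueError("cv must be >= 0")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ValueError("outlier_rate must lie in [0, 1]")
        for _, lost in self.discontinuities:
            if not (0.0 < lost < 1.0):
                raise ValueError("lost_fraction must lie in (0, 1)")


def params_at_concentration(
    C: float,
    g0: float = 0.025,
    theta_u: float = DEFAULT_THETA_U,
    theta_dox: float = 45000.0,
    N0: float = DEFAULT_SEED_DENSITY,
    n_doses: int = 1,
    coeffs: dict | None = None,
    fs_drift: float = 0.0,
    gamma_drift: float = 1.0,
) -> MultiDoseParams:
    """True treated-model parameters at a drug concentration.

    Per-dose drift (``fs`` additive, ``gamma_d`` multiplicative) emulates
    acquired resistance over successive doses; drift of (0, 1) gives a
    constant parameterization.
    """
    coeffs = coeffs or DEFAULT_TRUE_COEFFS
    vals = {k: float(eval_form(form, a, C)) for k, (form, a) in coeffs.items()}
    fs1 = float(np.clip(vals["fs"], 0.0, 1.0))
    g1 = max(vals["gamma_d"], 0.0)
    fs = [min(1.0, fs1 + i * fs_drift) for i in range(n_doses)]
    gamma = [g1 * gamma_drift**i for i in range(n_doses)]
    mode = "constant" if (fs_drift == 0.0 and gamma_drift == 1.0) or n_doses == 1 else "adaptive"
    return MultiDoseParams(
        g0=g0, gs=max(vals["gs"], 0.0), gd=max(vals["gd"], 0.0), kd=vals["kd"],
        theta_u=theta_u, theta_dox=theta_dox,
        fs=fs, gamma_d=gamma, N0=N0,
        mode=mode if n_doses > 1 else "constant",
    )


def generate_replicate(
    params: MultiDoseParams,
    schedule: TreatmentSchedule,
    cadence_h: float = 3.0,
    horizon_h: float = 504.0,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | int | None = None,
    replicate_id: str = "synthetic",
    condition: Condition | None = None,
) -> tuple[TimeCourse, dict]:
    """Simulate one replicate and corrupt it with the configured artifacts.

    Returns the observed time course and a truth record holding the
    generating parameters, the noise-free counts, and an artifact log
    (outlier indices, discontinuity indices and factors).
    """
    noise = noise or NoiseModel(multiplicative_cv=0.0)
    rng = np.random.default_rng(rng)
    t_grid = np.arange(0.0, horizon_h + 0.5 * cadence_h, cadence_h)
    traj = dynamics.simulate(params, schedule, t_grid)
    truth_N = traj.N.copy()

    observed = truth_N.copy()
    if noise.multiplicative_cv > 0:
        sigma = np.sqrt(np.log1p(noise.multiplicative_cv**2))
        observed = observed * rng.lognormal(-0.5 * sigma**2, sigma, size=observed.size)

    outlier_idx: list[int] = []
    if noise.outlier_rate > 0:
        hits = rng.random(observed.size) < noise.outlier_rate
        # never corrupt the endpoints the normalization needs
        hits[:2] = hits[-2:] = False
        outlier_idx = list(np.nonzero(hits)[0])
        observed[hits] *= noise.outlier_scale

    disc_log: list[dict] = []
    for t_disc, lost in noise.discontinuities:
        d = int(np.searchsorted(t_grid, t_disc))
        if d < 2 or d > observed.size - 2:
            raise ValueError(f"discontinuity at {t_disc} h lacks usable neighbors")
        observed[:d] *= 1.0 / (1.0 - lost)
        disc_log.append({"index": d, "time": float(t_grid[d]), "lost_fraction": lost})

    condition = condition or Condition(0, float(schedule.concentrations[0]) if schedule.n_doses else 0.0, None, schedule.n_doses)
    tc = TimeCourse(t_grid, observed, replicate_id, condition)
    truth = {
        "params": params.as_dict(),
        "dose_times": list(map(float, schedule.dose_times)),
        "concentrations": list(map(float, schedule.concentrations)),
        "truth_counts": truth_N,
        "outlier_indices": outlier_idx,
        "discontinuities": disc_log,
    }
    return tc, truth


def _condition_schedule(cond: Condition, first_dose_h: float) -> TreatmentSchedule:
    if cond.concentration_nM == 0.0:
        return TreatmentSchedule.empty()
    interval_h = (cond.interval_d or 0.0) * HOURS_PER_DAY
    return TreatmentSchedule.regular(
        first_dose_h, interval_h, cond.n_doses, cond.concentration_nM
    )


def generate_experiment(
    design: int,
    seed: int,
    formulas: dict | None = None,
    noise: NoiseModel | None = None,
    cadence_h: float = 3.0,
    post_window_h: float = 336.0,
    first_dose_h: float = DEFAULT_FIRST_DOSE_H,
    adaptive_threshold_d: float = 8.0,
    fs_drift: float = 0.05,
    gamma_drift: float = 0.7,
    **param_kwargs,
) -> tuple[list[TimeCourse], list[dict]]:
    """Generate a full replicate set for one experimental design.

    Conditions with inter-treatment intervals of at least
    ``adaptive_threshold_d`` days get per-dose drift in (fs, gamma_d),
    emulating the acquired-resistance regime; shorter intervals use constant
    parameters. The truth record of every replicate is returned alongside.
    """
    if design not in DESIGN_TABLE:
        raise ValueError(f"unknown design {design!r}")
    entries = enumerate_design(design)
    ss = np.random.SeedSequence([seed, design])
    children = ss.spawn(len(entries))
    tcs: list[TimeCourse] = []
    truths: list[dict] = []
    for (cond, rep_id), child in zip(entries, children):
        schedule = _condition_schedule(cond, first_dose_h)
        interval_d = cond.interval_d or 0.0
        adaptive = cond.n_doses > 1 and interval_d >= adaptive_threshold_d
        params = params_at_concentration(
            cond.concentration_nM,
            n_doses=schedule.n_doses,
            coeffs=formulas,
            fs_drift=fs_drift if adaptive else 0.0,
            gamma_drift=gamma_drift if adaptive else 1.0,
            **param_kwargs,
        )
        horizon = first_dose_h + post_window_h
        if schedule.n_doses:
            horizon = float(schedule.dose_times[-1]) + post_window_h
        tc, truth = generate_replicate(
            params,
            schedule,
            cadence_h=cadence_h,
            horizon_h=horizon,
            noise=noise,
            rng=np.random.default_rng(child),
            replicate_id=rep_id,
            condition=cond,
        )
        truth["replicate_id"] = rep_id
        truth["condition"] = list(cond.as_tuple())
        tcs.append(tc)
        truths.append(truth)
    return tcs, truths
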