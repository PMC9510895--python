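"""Forward simulation of untreated, single-dose, and multiple-dose dynamics.

The treated model is a hybrid system: logistic growth with capacity
``theta_u`` before the first dose; at each dose time the proliferating
compartment is split into survivors and a fresh irreversibly-damaged
subpopulation; between doses all compartments share the treated capacity
``theta_dox`` and are coupled through the total count. Damaged subpopulation
``i`` grows at a rate decaying exponentially from ``gd`` toward ``kd``
(negative ``kd`` means net death).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .data_model import MultiDoseParams, StateTrajectory, TreatmentSchedule

__all__ = [
    "logistic_closed_form",
    "damaged_rate",
    "apply_dose_partition",
    "simulate",
    "SimulationError",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-4  # cells


class SimulationError(RuntimeError):
    pass


def logistic_closed_form(N0: float, g: float, theta: float, t) -> np.ndarray:
    """Analytic logistic solution theta*N0*e^{gt} / (theta + N0*(e^{gt}-1))."""
    t = np.asarray(t, dtype=float)
    e = np.exp(g * t)
    return theta * N0 * e / (theta + N0 * (e - 1.0))


def damaged_rate(t, t_dose: float, gd: float, kd: float, gamma_d: float):
    """Net per-capita rate prefactor of a damaged subpopulation at time t."""
    return kd + (gd - kd) * np.exp(-gamma_d * (np.asarray(t, dtype=float) - t_dose))


def apply_dose_partition(S_minus: float, fs_i: float) -> tuple[float, float]:
    """Split the proliferating pool at a dose: survivors and newly damaged."""
    if not (0.0 <= fs_i <= 1.0):
        raise ValueError("fs must lie in [0, 1]")
    if S_minus < 0:
        raise ValueError("cell count must be nonnegative")
    S_plus = fs_i * S_minus
    return S_plus, S_minus - S_plus


def _segment_rhs(t, y, live, t_doses, gs, gd, kd, gamma_d, theta_dox):
    # y = [S, D_1 .. D_k] for the k spawned compartments
    N = y.sum()
    crowd = 1.0 - N / theta_dox
    dy = np.empty_like(y)
    dy[0] = gs * y[0] * crowd
    for j, i in enumerate(live):
        rate = kd + (gd - kd) * np.exp(-gamma_d[i] * (t - t_doses[i]))
        dy[j + 1] = rate * y[j + 1] * crowd
    return dy


def _integrate_segment(fun, t0, t1, y0, t_eval, rtol, atol):
    """Integrate on [t0, t1]; return values at t_eval and the state at t1."""
    if t1 <= t0:
        return np.empty((len(y0), 0)), np.asarray(y0, dtype=float)
    t_eval = np.asarray(t_eval, dtype=float)
    appended = t_eval.size == 0 or t_eval[-1] < t1
    t_req = np.append(t_eval, t1) if appended else t_eval
    sol = solve_ivp(
        fun, (t0, t1), y0, method="RK45", t_eval=t_req, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SimulationError(f"integration failed on [{t0:g}, {t1:g}]: {sol.message}")
    y_end = sol.y[:, -1]
    y_eval = sol.y[:, :-1] if appended else sol.y
    return y_eval, y_end


def simulate(
    params: MultiDoseParams,
    schedule: TreatmentSchedule,
    t_grid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> StateTrajectory:
    """Simulate the hybrid treated model on ``t_grid`` (hours).

    Integration proceeds segment-by-segment between dose times with an
    adaptive explicit Runge-Kutta 4(5) scheme. At each dose time the
    proliferating pool is partitioned (for the first dose, the whole
    population); coincident dose times are applied sequentially in schedule
    order. Grid points falling exactly on a dose time report the post-dose
    state (Heaviside convention H(0) = 1); the total count is continuous
    across doses regardless.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a nonempty strictly increasing 1-D array")
    nd = schedule.n_doses
    if nd != params.n_doses:
        raise ValueError(
            f"schedule has {nd} doses but params carry {params.n_doses} per-dose values"
        )
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    t_doses = np.asarray(schedule.dose_times, dtype=float)
    if nd and (t_doses[0] < t0 or t_doses[-1] > t_end):
        raise ValueError("dose times must lie within the simulation window")

    S_out = np.full(t_grid.size, np.nan)
    D_out = np.zeros((nd, t_grid.size))

    # --- untreated phase: logistic with (g0, theta_u) ---
    t_first = t_doses[0] if nd else t_end
    pre_mask = t_grid < t_first if nd else np.ones_like(t_grid, dtype=bool)

    def untreated_rhs(t, y):
        return [params.g0 * y[0] * (1.0 - y[0] / params.theta_u)]

    y_eval, y_end = _integrate_segment(
        untreated_rhs, t0, t_first, [params.N0], t_grid[pre_mask], rtol, atol
    )
    if pre_mask.any():
        S_out[pre_mask] = y_eval[0]
    N_pre = float(y_end[0])

    if nd == 0:
        traj = StateTrajectory(t_grid, S_out, D_out, S_out.copy())
        _check_state(traj, atol=atol)
        return traj

    # --- treated phase: event-partition then integrate between doses ---
    fs = np.asarray(params.fs, dtype=float)
    gamma_d = np.asarray(params.gamma_d, dtype=float)
    S = N_pre
    D = np.zeros(nd)
    live: list[int] = []

    boundaries = np.concatenate([t_doses, [t_end]])
    i = 0
    while i < nd:
        # apply every dose scheduled at this instant, sequentially
        t_ev = t_doses[i]
        while i < nd and t_doses[i] == t_ev:
            S, D_new = apply_dose_partition(S, fs[i])
            D[i] = D_new
            live.append(i)
            i += 1
        t_next = boundaries[i] if i < nd else t_end
        last_segment = i >= nd
        if last_segment:
            seg_mask = (t_grid >= t_ev) & (t_grid <= t_next)
        else:
            seg_mask = (t_grid >= t_ev) & (t_grid < t_next)
        y0 = np.concatenate([[S], D[live]])
        live_now = list(live)

        def rhs(t, y, _live=live_now):
            return _segment_rhs(
                t, y, _live, t_doses, params.gs, params.gd, params.kd,
                gamma_d, params.theta_dox,
            )

        y_eval, y_end = _integrate_segment(
            rhs, t_ev, t_next, y0, t_grid[seg_mask], rtol, atol
        )
        if seg_mask.any():
            S_out[seg_mask] = y_eval[0]
            for j, k in enumerate(live_now):
                D_out[k, seg_mask] = y_eval[j + 1]
        # exact-hit segments of zero length keep state
        S = float(y_end[0])
        for j, k in enumerate(live_now):
            D[k] = float(y_end[j + 1])

    N_out = S_out + D_out.sum(axis=0)
    traj = StateTrajectory(t_grid, S_out, D_out, N_out)
    _check_state(traj, atol=atol)
    return traj


def _check_state(traj: StateTrajectory, tol: float = 1e-6, atol: float = DEFAULT_ATOL) -> None:
    # integration can undershoot zero by O(atol) on decaying compartments
    floor = -(tol * max(1.0, np.nanmax(traj.N)) + 10.0 * atol)
    if np.nanmin(traj.S) < floor or (traj.D.size and traj.D.min() < floor):
        raise SimulationError("negative compartment beyond solver tolerance")
    np.clip(traj.S, 0.0, None, out=traj.S)
    np.clip(traj.D, 0.0, None, out=traj.D)
    traj.N = traj.S + traj.D.sum(axis=0)
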