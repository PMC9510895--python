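"""Shared domain types, tabular I/O, and experiment-design enumeration.

Canonical units throughout the package: hours for time, nM for drug
concentration, cells for counts, 1/h for rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "TimeCourse",
    "TreatmentSchedule",
    "UntreatedParams",
    "MultiDoseParams",
    "StateTrajectory",
    "FitResult",
    "read_time_courses",
    "write_time_courses",
    "enumerate_design",
    "DESIGN_TABLE",
    "HOURS_PER_DAY",
]

HOURS_PER_DAY = 24.0

#: Experimental designs: per experiment, the tested concentrations (nM),
#: inter-treatment intervals (days), dose numbers, and replicates per condition.
DESIGN_TABLE = {
    1: {
        "concentrations_nM": (0.0, 10.0, 20.0, 35.0, 50.0, 75.0, 100.0, 125.0, 150.0, 300.0),
        "intervals_d": (None,),
        "n_doses": (1,),
        "replicates": 6,
    },
    2: {
        "concentrations_nM": (75.0,),
        "intervals_d": (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0),
        "n_doses": (2,),
        "replicates": 12,
    },
    3: {
        "concentrations_nM": (75.0,),
        "intervals_d": (2.0, 14.0),
        "n_doses": (1, 2, 3, 4, 5),
        "replicates": 12,
    },
}


class SchemaError(ValueError):
    """Raised when an input table does not match the declared column schema."""


class ValidationError(ValueError):
    """Raised when domain-type invariants are violated."""


@dataclass(frozen=True)
class Condition:
    """Flat condition key shared by all three experimental designs."""

    experiment_id: int
    concentration_nM: float
    interval_d: float | None
    n_doses: int

    def as_tuple(self) -> tuple:
        return (self.experiment_id, self.concentration_nM, self.interval_d, self.n_doses)


@dataclass
class TimeCourse:
    """One replicate's observed (time, count) series with condition metadata.

    Parameters
    ----------
    times : array of float
        Observation times in hours, strictly increasing.
    counts : array of float
        Estimated cell counts (nonnegative reals; image-derived estimates
        need not be integers).
    replicate_id : str
        Well/replicate label.
    condition : Condition
        Experimental condition key.
    flags : list of str, optional
        Per-point provenance flags (``raw``, ``normalized``, ``truncated-at``,
        ``outlier-removed``).
    """

    times: np.ndarray
    counts: np.ndarray
    replicate_id: str
    condition: Condition
    flags: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValidationError(
                f"replicate {self.replicate_id}: times and counts differ in length"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"replicate {self.replicate_id}: times not strictly increasing"
            )
        if np.any(self.counts < 0):
            raise ValidationError(f"replicate {self.replicate_id}: negative counts")
        if not self.flags:
            self.flags = ["raw"] * self.times.size

    def __len__(self) -> int:
        return int(self.times.size)

    def subset(self, mask: np.ndarray, flag: str | None = None) -> "TimeCourse":
        """Return a copy restricted to ``mask``; optionally tag survivors."""
        mask = np.asarray(mask, dtype=bool)
        flags = [f for f, keep in zip(self.flags, mask) if keep]
        if flag is not None:
            flags = [flag for _ in flags]
        return replace(
            self,
            times=self.times[mask].copy(),
            counts=self.counts[mask].copy(),
            flags=flags,
            warnings=list(self.warnings),
        )


@dataclass
class TreatmentSchedule:
    """Ordered dose times (hours) with per-dose concentrations (nM)."""

    dose_times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.dose_times = np.atleast_1d(np.asarray(self.dose_times, dtype=float))
        self.concentrations = np.atleast_1d(np.asarray(self.concentrations, dtype=float))
        if self.dose_times.size != self.concentrations.size:
            raise ValidationError("dose_times and concentrations differ in length")
        if self.dose_times.size and np.any(np.diff(self.dose_times) < 0):
            raise ValidationError("dose_times must be nondecreasing")

    @property
    def n_doses(self) -> int:
        return int(self.dose_times.size)

    @classmethod
    def regular(
        cls, first_dose_h: float, interval_h: float, n_doses: int, concentration_nM: float
    ) -> "TreatmentSchedule":
        times = first_dose_h + interval_h * np.arange(n_doses, dtype=float)
        return cls(times, np.full(n_doses, float(concentration_nM)))

    @classmethod
    def empty(cls) -> "TreatmentSchedule":
        return cls(np.empty(0), np.empty(0))


@dataclass
class UntreatedParams:
    """Logistic growth parameters for untreated cells."""

    g0: float  # proliferation rate, 1/h
    theta_u: float  # carrying capacity, cells
    N0: float  # initial count, cells

    def __post_init__(self) -> None:
        if self.g0 < 0:
            raise ValidationError("g0 must be >= 0")
        if self.theta_u <= 0 or self.N0 <= 0:
            raise ValidationError("theta_u and N0 must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {"g0": self.g0, "theta_u": self.theta_u, "N0": self.N0}


@dataclass
class MultiDoseParams:
    """Full parameterization of the treated model; single-dose is ``n_d = 1``.

    ``kd`` is the asymptotic net rate of damaged cells: negative values denote
    net death. In ``constant`` mode the per-dose lists ``fs`` and ``gamma_d``
    hold one replicated value.
    """

    g0: float
    gs: float
    gd: float
    kd: float
    theta_u: float
    theta_dox: float
    fs: Sequence[float]
    gamma_d: Sequence[float]
    N0: float
    mode: str = "adaptive"  # "constant" | "adaptive"

    def __post_init__(self) -> None:
        self.fs = list(map(float, np.atleast_1d(self.fs)))
        self.gamma_d = list(map(float, np.atleast_1d(self.gamma_d)))
        if len(self.fs) != len(self.gamma_d):
            raise ValidationError("fs and gamma_d must have equal length")
        if any(not (0.0 <= f <= 1.0) for f in self.fs):
            raise ValidationError("each fs must lie in [0, 1]")
        if any(g < 0 for g in self.gamma_d):
            raise ValidationError("each gamma_d must be >= 0")
        if self.theta_dox <= 0 or self.theta_u <= 0:
            raise ValidationError("carrying capacities must be > 0")
        if self.N0 <= 0:
            raise ValidationError("N0 must be > 0")
        if self.mode not in ("constant", "adaptive"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "constant":
            if len(set(self.fs)) > 1 or len(set(self.gamma_d)) > 1:
                raise ValidationError("constant mode requires equal per-dose values")

    @property
    def n_doses(self) -> int:
        return len(self.fs)

    def as_dict(self) -> dict:
        return {
            "g0": self.g0, "gs": self.gs, "gd": self.gd, "kd": self.kd,
            "theta_u": self.theta_u, "theta_dox": self.theta_dox,
            "fs": list(self.fs), "gamma_d": list(self.gamma_d),
            "N0": self.N0, "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultiDoseParams":
        return cls(**d)


@dataclass
class StateTrajectory:
    """Simulated compartment trajectories on a time grid.

    ``D`` has one row per damaged subpopulation, zero before its dose time;
    ``N`` is the total count (surviving plus all spawned damaged compartments).
    """

    times: np.ndarray
    S: np.ndarray
    D: np.ndarray  # shape (n_doses, len(times))
    N: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "S": self.S}
        for i in range(self.D.shape[0]):
            data[f"D{i + 1}"] = self.D[i]
        data["N"] = self.N
        return pd.DataFrame(data)


@dataclass
class FitResult:
    """Outcome of one least-squares calibration."""

    params: UntreatedParams | MultiDoseParams
    free_names: list[str]
    estimates: np.ndarray  # free-parameter vector, same order as free_names
    param_ci: dict[str, tuple[float, float]]
    fixed_params: dict[str, float]
    residuals: np.ndarray
    gof: dict[str, float]
    convergence: dict
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_flags: dict[str, str] = field(default_factory=dict)
    # retained context so downstream passes (theta_dox policy) can refit
    time_course: TimeCourse | None = None
    schedule: TreatmentSchedule | None = None

    @property
    def last_observed_count(self) -> float:
        if self.time_course is None:
            raise ValueError("fit carries no source time course")
        return float(self.time_course.counts[-1])

    def param_value(self, name: str) -> float:
        if name in self.fixed_params:
            return self.fixed_params[name]
        return float(self.estimates[self.free_names.index(name)])

    def to_json_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "free_names": self.free_names,
            "estimates": [float(v) for v in self.estimates],
            "param_ci": {k: [float(a), float(b)] for k, (a, b) in self.param_ci.items()},
            "fixed_params": {k: float(v) for k, v in self.fixed_params.items()},
            "gof": {k: float(v) for k, v in self.gof.items()},
            "convergence": {
                k: (v if isinstance(v, (str, bool, type(None))) else float(v))
                for k, v in self.convergence.items()
            },
            "ci_flags": dict(self.ci_flags),
            "replicate_id": None if self.time_course is None else self.time_course.replicate_id,
            "condition": None
            if self.time_course is None
            else list(self.time_course.condition.as_tuple()),
        }


# ---------------------------------------------------------------------------
# Tabular I/O

_REQUIRED_COLUMNS = (
    "time",
    "count",
    "replicate",
    "experiment",
    "concentration_nM",
    "interval_d",
    "n_doses",
)

_TIME_UNIT_FACTORS = {"hours": 1.0, "h": 1.0, "days": HOURS_PER_DAY, "d": HOURS_PER_DAY}


def read_time_courses(
    path, schema: dict | None = None, time_unit: str = "hours"
) -> list[TimeCourse]:
    """Read replicate time courses from a CSV table.

    Parameters
    ----------
    path : str or file-like
        CSV with columns ``time,count,replicate,experiment,concentration_nM,
        interval_d,n_doses`` (remappable via ``schema``).
    schema : dict, optional
        Mapping from canonical column names to the file's column names.
    time_unit : {"hours", "days"}
        Unit of the time column; days are converted to hours.
    """
    if time_unit not in _TIME_UNIT_FACTORS:
        raise SchemaError(f"unknown time unit {time_unit!r}")
    factor = _TIME_UNIT_FACTORS[time_unit]
    df = pd.read_csv(path)
    colmap = {name: name for name in _REQUIRED_COLUMNS}
    if schema:
        colmap.update(schema)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    out: list[TimeCourse] = []
    keys = ["replicate", "experiment", "concentration_nM", "interval_d", "n_doses"]
    for (rep, exp, conc, interval, nd), grp in df.groupby(keys, sort=True, dropna=False):
        grp = grp.sort_values("time", kind="stable")
        times = grp["time"].to_numpy(dtype=float) * factor
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"replicate {rep!r}: non-monotone time values")
        interval_val = None if pd.isna(interval) else float(interval)
        cond = Condition(int(exp), float(conc), interval_val, int(nd))
        out.append(
            TimeCourse(times, grp["count"].to_numpy(dtype=float), str(rep), cond)
        )
    return out


def write_time_courses(path, time_courses: Iterable[TimeCourse]) -> None:
    """Write time courses to the canonical CSV layout (times in hours)."""
    rows = []
    for tc in time_courses:
        c = tc.condition
        for t, n in zip(tc.times, tc.counts):
            rows.append(
                {
                    "time": t,
                    "count": n,
                    "replicate": tc.replicate_id,
                    "experiment": c.experiment_id,
                    "concentration_nM": c.concentration_nM,
                    "interval_d": "" if c.interval_d is None else c.interval_d,
                    "n_doses": c.n_doses,
                }
            )
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)


def enumerate_design(experiment_id: int) -> list[tuple[Condition, str]]:
    """Enumerate (condition, replicate_id) pairs for one experimental design.

    Sizes follow the published design table: Experiment 1 crosses 10
    concentrations with 6 replicates (60), Experiment 2 crosses 9 intervals
    with 12 replicates (108), and Experiment 3 crosses 2 intervals and 5 dose
    numbers with 12 replicates (120).
    """
    if experiment_id not in DESIGN_TABLE:
        raise ValueError(f"unknown experiment id {experiment_id!r}")
    row = DESIGN_TABLE[experiment_id]
    out: list[tuple[Condition, str]] = []
    for conc in row["concentrations_nM"]:
        for interval in row["intervals_d"]:
            for nd in row["n_doses"]:
                for r in range(row["replicates"]):
                    cond = Condition(experiment_id, conc, interval, nd)
                    rep_id = (
                        f"E{experiment_id}_C{conc:g}_I{'-' if interval is None else f'{interval:g}'}"
                        f"_D{nd}_R{r + 1}"
                    )
                    out.append((cond, rep_id))
    return out


def write_fit_results(path, fits: Iterable[FitResult]) -> None:
    with open(path, "w") as fh:
        json.dump([f.to_json_dict() for f in fits], fh, indent=1)
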