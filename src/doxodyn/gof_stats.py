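"""Quality-of-fit metrics, rank-sum testing, and model-version comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GofReport",
    "nrmse",
    "ccc",
    "r2_pcc",
    "gof_report",
    "wilcoxon_rank_sum",
    "ModelComparison",
    "compare_model_versions",
]


@dataclass(frozen=True)
class GofReport:
    nrmse: float  # percent
    r2: float
    pcc: float
    ccc: float
    n_points: int

    def as_dict(self) -> dict[str, float]:
        return {
            "nrmse": self.nrmse, "r2": self.r2, "pcc": self.pcc,
            "ccc": self.ccc, "n_points": self.n_points,
        }


def _check_pair(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("obs and pred must be equal-length 1-D arrays with >= 2 points")
    return obs, pred


def nrmse(obs, pred) -> float:
    """Root mean squared error normalized by mean(obs), as a percent."""
    obs, pred = _check_pair(obs, pred)
    m = obs.mean()
    if m == 0:
        raise ValueError("mean of observations is zero; NRMSE undefined")
    return float(100.0 * np.sqrt(np.mean((pred - obs) ** 2)) / m)


def ccc(obs, pred) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments."""
    obs, pred = _check_pair(obs, pred)
    vx, vy = obs.var(), pred.var()
    if vx == 0 or vy == 0:
        raise ValueError("zero variance; CCC undefined")
    sxy = np.mean((obs - obs.mean()) * (pred - pred.mean()))
    return float(2.0 * sxy / (vx + vy + (obs.mean() - pred.mean()) ** 2))


def r2_pcc(obs, pred) -> tuple[float, float]:
    """Coefficient of determination (1 - RSS/TSS) and Pearson correlation."""
    obs, pred = _check_pair(obs, pred)
    tss = np.sum((obs - obs.mean()) ** 2)
    if tss == 0:
        raise ValueError("zero total sum of squares; R^2 undefined")
    r2 = 1.0 - np.sum((pred - obs) ** 2) / tss
    if pred.var() == 0:  # correlation undefined against a flat prediction
        return float(r2), float("nan")
    pcc = stats.pearsonr(obs, pred).statistic
    return float(r2), float(pcc)


def gof_report(obs, pred) -> GofReport:
    r2, pcc = r2_pcc(obs, pred)
    return GofReport(nrmse(obs, pred), r2, pcc, ccc(obs, pred), len(np.asarray(obs)))


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p-value.

    Uses the exact null distribution when the pooled sample has at most 20
    observations and no ties; otherwise a normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs >= 3 observations")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class ModelComparison:
    group: tuple
    p_value: float
    median_constant: float
    median_adaptive: float
    decision: str  # "constant" | "adaptive"

    def as_dict(self) -> dict:
        return {
            "group": list(self.group),
            "p_value": self.p_value,
            "median_constant": self.median_constant,
            "median_adaptive": self.median_adaptive,
            "decision": self.decision,
        }


def compare_model_versions(
    fits_constant, fits_adaptive, alpha: float = 0.05
) -> list[ModelComparison]:
    """Decide constant vs adaptive parameterization per condition group.

    For each condition, the per-replicate NRMSE distributions of the two model
    versions are compared with a two-sided rank-sum test; ``adaptive`` is
    selected only when its NRMSE is significantly lower at level ``alpha``.
    """
    def keyed(fits):
        out: dict[tuple, dict[str, float]] = {}
        for f in fits:
            if f.time_course is None:
                raise ValueError("fit lacks source time course metadata")
            key = f.time_course.condition.as_tuple()
            out.setdefault(key, {})[f.time_course.replicate_id] = f.gof["nrmse"]
        return out

    const, adapt = keyed(fits_constant), keyed(fits_adaptive)
    if set(const) != set(adapt):
        raise ValueError("constant and adaptive fits cover different condition groups")
    results = []
    for key in sorted(const, key=lambda k: tuple(str(v) for v in k)):
        if set(const[key]) != set(adapt[key]):
            raise ValueError(f"replicate sets differ within group {key}")
        reps = sorted(const[key])
        nc = np.array([const[key][r] for r in reps])
        na = np.array([adapt[key][r] for r in reps])
        if np.array_equal(nc, na):
            p = 1.0
        else:
            p = wilcoxon_rank_sum(nc, na)
        med_c, med_a = float(np.median(nc)), float(np.median(na))
        decision = "adaptive" if (p < alpha and med_a < med_c) else "constant"
        results.append(ModelComparison(key, p, med_c, med_a, decision))
    return results
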