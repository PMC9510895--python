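"""Trajectory cleaning: truncation, discontinuity normalization, outlier removal.

Media handling during long imaging runs produces step discontinuities in the
estimated counts. Drops losing less than half of the cells are repaired by
rescaling the pre-gap prefix with a constant chosen to smooth the first and
second derivatives across the gap; larger drops, confluence plateaus, and
runs of repeated discontinuities truncate the series instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import TimeCourse

__all__ = [
    "Discontinuity",
    "TruncationReport",
    "truncate",
    "detect_discontinuities",
    "normalization_constant",
    "normalize_discontinuity",
    "remove_outliers",
    "preprocess",
    "NormalizationError",
    "UnusableTrajectoryError",
]

MAD_SCALE = 1.4826  # consistency factor for normal data


class NormalizationError(ValueError):
    pass


class UnusableTrajectoryError(ValueError):
    pass


@dataclass(frozen=True)
class Discontinuity:
    index: int  # index d of the first post-drop point
    drop_fraction: float
    klass: str  # "minor" (<50% lost) | "major" (>=50%)


@dataclass
class TruncationReport:
    rule: str  # "none" | "confluence" | "major-drop" | "repeated-discontinuities"
    cut_index: int | None = None
    alphas: dict[int, float] = field(default_factory=dict)
    removed_indices: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "cut_index": None if self.cut_index is None else int(self.cut_index),
            "alphas": {str(k): float(v) for k, v in self.alphas.items()},
            "removed_indices": [int(i) for i in self.removed_indices],
        }


def detect_discontinuities(tc: TimeCourse, min_drop: float = 0.20) -> list[Discontinuity]:
    """Find indices where the count drops by at least ``min_drop`` in one step.

    Only indices with valid d-2 and d+1 neighbors are reported, since the
    normalization constant needs both. Drops of >= 50% are classed ``major``.
    """
    if len(tc) < 4:
        raise ValueError("need at least 4 points")
    out = []
    n = tc.counts
    for d in range(2, len(tc) - 1):
        if n[d - 1] <= 0:
            continue
        drop = 1.0 - n[d] / n[d - 1]
        if drop >= min_drop:
            out.append(
                Discontinuity(d, float(drop), "major" if drop >= 0.5 else "minor")
            )
    return out


def truncate(
    tc: TimeCourse,
    theta_ref: float,
    confluence_frac: float = 0.95,
    major_drop_frac: float = 0.50,
    min_drop: float = 0.20,
    repeat_count: int = 3,
    repeat_window: int = 20,
) -> tuple[TimeCourse, TruncationReport]:
    """Truncate a series at confluence, a major drop, or repeated discontinuities.

    The cut is placed at the earliest of: (a) the first index whose count
    reaches ``confluence_frac * theta_ref``; (b) the first single-step drop of
    at least ``major_drop_frac``; (c) the onset of ``repeat_count`` minor
    discontinuities within any ``repeat_window``-point window. Returns the
    retained prefix and a report naming the rule that fired.
    """
    if not (0.0 < confluence_frac <= 1.0):
        raise ValueError("confluence_frac must lie in (0, 1]")
    n = tc.counts
    candidates: list[tuple[int, str]] = []

    conf = np.nonzero(n >= confluence_frac * theta_ref)[0]
    if conf.size:
        candidates.append((int(conf[0]), "confluence"))

    with np.errstate(divide="ignore", invalid="ignore"):
        drops = 1.0 - n[1:] / n[:-1]
    major = np.nonzero(drops >= major_drop_frac)[0]
    if major.size:
        candidates.append((int(major[0]) + 1, "major-drop"))

    minor_idx = [
        d.index
        for d in (detect_discontinuities(tc, min_drop) if len(tc) >= 4 else [])
        if d.klass == "minor"
        and _persistent_level_shift(tc.counts, d.index, min_drop, major_drop_frac)
    ]
    for k in range(len(minor_idx) - repeat_count + 1):
        if minor_idx[k + repeat_count - 1] - minor_idx[k] < repeat_window:
            candidates.append((minor_idx[k], "repeated-discontinuities"))
            break

    if not candidates:
        return tc, TruncationReport("none", None)
    cut, rule = min(candidates, key=lambda c: (c[0], c[1]))
    if cut < 4:
        raise UnusableTrajectoryError(
            f"replicate {tc.replicate_id}: truncation at index {cut} leaves <4 points"
        )
    mask = np.zeros(len(tc), dtype=bool)
    mask[:cut] = True
    out = tc.subset(mask)
    out.flags = [f if f != "raw" else "raw" for f in out.flags]
    return out, TruncationReport(rule, cut)


def normalization_constant(tc: TimeCourse, d: int) -> float:
    """Derivative-smoothing rescaling constant for the prefix before index d.

    alpha = [ (N_{d-1}-N_{d-2})/(t_{d-1}-t_{d-2}) + 2 N_{d-1}/(t_d-t_{d-1}) ]
          / [ 2 N_d/(t_d-t_{d-1}) + (N_d-N_{d+1})/(t_{d+1}-t_d) ]

    Equals 1 on a constant series; on a series whose prefix was scaled by c it
    recovers approximately c when slopes are small relative to 2N/dt.
    """
    if not (2 <= d <= len(tc) - 2):
        raise ValueError(f"index {d} lacks d-2 or d+1 neighbors")
    t, n = tc.times, tc.counts
    dt_pre = t[d - 1] - t[d - 2]
    dt_gap = t[d] - t[d - 1]
    dt_post = t[d + 1] - t[d]
    if min(dt_pre, dt_gap, dt_post) <= 0:
        raise NormalizationError("nonpositive time step around discontinuity")
    num = (n[d - 1] - n[d - 2]) / dt_pre + 2.0 * n[d - 1] / dt_gap
    den = 2.0 * n[d] / dt_gap + (n[d] - n[d + 1]) / dt_post
    if den == 0 or not np.isfinite(num / den) or num / den <= 0:
        raise NormalizationError(
            f"replicate {tc.replicate_id}: nonpositive normalization constant at {d}"
        )
    return float(num / den)


def normalize_discontinuity(tc: TimeCourse, d: int) -> tuple[TimeCourse, float]:
    """Divide counts before index d by the smoothing constant; flag the prefix."""
    alpha = normalization_constant(tc, d)
    counts = tc.counts.copy()
    counts[:d] = counts[:d] / alpha
    out = TimeCourse(
        tc.times.copy(),
        counts,
        tc.replicate_id,
        tc.condition,
        flags=["normalized" if i < d else f for i, f in enumerate(tc.flags)],
        warnings=list(tc.warnings),
    )
    return out, alpha


def remove_outliers(
    tc: TimeCourse,
    window: int = 5,
    n_mad: float = 3.0,
    max_removed_frac: float = 0.10,
) -> tuple[TimeCourse, list[int]]:
    """Drop points deviating from the centered moving median by > n_mad scaled MADs.

    Windows with zero MAD remove nothing (plateaus are data, not outliers).
    Removed points are dropped outright, never interpolated. If more than
    ``max_removed_frac`` of points would be removed, the result carries a
    warning flag.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if n_mad <= 0:
        raise ValueError("n_mad must be > 0")
    n = tc.counts
    half = window // 2
    keep = np.ones(len(tc), dtype=bool)
    for i in range(len(tc)):
        lo, hi = max(0, i - half), min(len(tc), i + half + 1)
        w = n[lo:hi]
        med = np.median(w)
        mad = MAD_SCALE * np.median(np.abs(w - med))
        if mad > 0 and abs(n[i] - med) > n_mad * mad:
            keep[i] = False
    removed = [int(i) for i in np.nonzero(~keep)[0]]
    if keep.sum() < 4:
        raise UnusableTrajectoryError(
            f"replicate {tc.replicate_id}: outlier removal leaves <4 points"
        )
    out = tc.subset(keep)
    if len(removed) > max_removed_frac * len(tc):
        out.warnings.append(
            f"outlier filter removed {len(removed)}/{len(tc)} points "
            f"(> {max_removed_frac:.0%})"
        )
    return out, removed


def _persistent_level_shift(
    counts: np.ndarray, d: int, min_drop: float, major_drop_frac: float
) -> bool:
    """True when the drop at d is a sustained level shift, not a lone outlier.

    Compares the median level over the three points on either side of the
    gap; an isolated spike or dip shifts only a single point and fails this
    check, leaving it for the outlier filter.
    """
    pre = np.median(counts[max(0, d - 3): d])
    post = np.median(counts[d: d + 3])
    if pre <= 0:
        return False
    drop = 1.0 - post / pre
    return min_drop <= drop < major_drop_frac


def preprocess(
    tc: TimeCourse,
    theta_ref: float,
    confluence_frac: float = 0.95,
    major_drop_frac: float = 0.50,
    min_drop: float = 0.20,
    window: int = 5,
    n_mad: float = 3.0,
) -> tuple[TimeCourse, TruncationReport]:
    """Full cleaning pipeline: truncate, normalize minor drops, remove outliers.

    Minor discontinuities are normalized left-to-right, re-detecting after each
    repair so the smoothing constant always uses repaired neighbors.
    """
    out, report = truncate(
        tc, theta_ref, confluence_frac=confluence_frac,
        major_drop_frac=major_drop_frac, min_drop=min_drop,
    )
    handled: set[int] = set()
    while True:
        discs = [
            disc for disc in detect_discontinuities(out, min_drop)
            if disc.klass == "minor"
            and disc.index not in handled
            and _persistent_level_shift(out.counts, disc.index, min_drop, major_drop_frac)
        ]
        if not discs:
            break
        d = discs[0].index
        try:
            out, alpha = normalize_discontinuity(out, d)
            report.alphas[d] = alpha
        except NormalizationError:
            pass
        handled.add(d)
    out, removed = remove_outliers(out, window=window, n_mad=n_mad)
    report.removed_indices = removed
    return out, report
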