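"""Behavioural quantifications for angular-velocity traces and 2-D paths.

Covers the turn ratio and side-preference measures used for open-loop
trackball recordings, fixed-arc-length path discretisation with per-segment
bearings and turn angles, the start-to-end directional error of a homing
path, circular mean +/- SE summaries, and an exact Wilcoxon signed-rank test
for the small samples typical of field experiments.

Conventions: angular velocity is signed with positive = right (clockwise)
turn; bearings are allocentric degrees from atan2; all angle differences are
wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .angles import wrap_deg
from .circuit_core import UndefinedAngleError


@dataclass(frozen=True)
class OmegaTrace:
    """Time-stamped signed angular-velocity series (deg/s, positive = right turn)."""

    time: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        w = np.asarray(self.omega, dtype=float)
        if t.ndim != 1 or t.shape != w.shape or len(t) == 0:
            raise ValueError("time and omega must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(w))):
            raise ValueError("trace contains non-finite values")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "omega", w)


@dataclass(frozen=True)
class PathTable:
    """Time-stamped 2-D trajectory."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or not (t.shape == x.shape == y.shape):
            raise ValueError("time, x, y must be equal-length 1-D arrays")
        if len(t) < 2:
            raise ValueError("a path needs at least 2 rows")
        for name, arr in (("time", t), ("x", x), ("y", y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class SegmentSeries:
    """Arc-length-resampled path: vertices, per-segment bearings, junction turn angles."""

    vertices: np.ndarray  # (m, 2)
    bearings: np.ndarray  # (m - 1,) degrees, allocentric
    turn_angles: np.ndarray  # (m - 2,) absolute degrees in [0, 180]
    resample_length: float


def _sample_dt(time: np.ndarray) -> np.ndarray:
    """Per-sample durations: half the span to each neighbour (one-sided at the ends)."""
    if len(time) == 1:
        return np.array([0.0])
    dt = np.empty_like(time)
    dt[1:-1] = (time[2:] - time[:-2]) / 2.0
    dt[0] = (time[1] - time[0]) / 2.0
    dt[-1] = (time[-1] - time[-2]) / 2.0
    return dt


def turn_ratio(trace: OmegaTrace) -> float:
    """(right - left) / (right + left) of integrated absolute angular velocity.

    Right and left angles are the trapezoidal integrals of |omega| over the
    positive and negative parts of the trace on its recorded grid.  Bounded in
    [-1, 1]; antisymmetric under a global sign flip; 0 if the trace never turns.
    """
    pos = np.clip(trace.omega, 0.0, None)
    neg = np.clip(-trace.omega, 0.0, None)
    if len(trace.time) == 1:
        right, left = float(pos[0]), float(neg[0])
    else:
        right = float(np.trapezoid(pos, trace.time))
        left = float(np.trapezoid(neg, trace.time))
    total = right + left
    if total == 0.0:
        return 0.0
    return (right - left) / total


def preferred_side_proportion(trace: OmegaTrace) -> float:
    """Fraction of turning time spent on the individual's preferred side.

    Each sample contributes its local duration to the side of its sign
    (omega == 0 samples are not turning); the preferred side is the one with
    more total turning time.  Returns a value in [0.5, 1]; ties (including a
    trace that never turns) give 0.5.
    """
    dt = _sample_dt(trace.time)
    right_t = float(dt[trace.omega > 0].sum())
    left_t = float(dt[trace.omega < 0].sum())
    total = right_t + left_t
    if total == 0.0 or right_t == left_t:
        return 0.5
    return max(right_t, left_t) / total


def discretise_path(path: PathTable, resample_length: float) -> SegmentSeries:
    """Resample a path at fixed arc length; derive bearings and turn angles.

    Vertices are placed by linear interpolation at cumulative arc lengths
    0, L, 2L, ...; a trailing remainder shorter than L is discarded.  Bearings
    are the atan2 direction of each segment; each junction's turn angle is the
    absolute wrapped difference of successive bearings, in [0, 180].
    """
    if resample_length <= 0:
        raise ValueError("resample_length must be > 0")
    xy = np.column_stack([path.x, path.y])
    seglen = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    if total < 2 * resample_length:
        raise ValueError(
            f"path too short to discretise: arc length {total:.6g} < "
            f"2 * resample_length = {2 * resample_length:.6g}"
        )
    n_seg = int(np.floor(total / resample_length + 1e-12))
    targets = np.arange(n_seg + 1) * resample_length
    vx = np.interp(targets, s, path.x)
    vy = np.interp(targets, s, path.y)
    vertices = np.column_stack([vx, vy])
    d = np.diff(vertices, axis=0)
    bearings = np.rad2deg(np.arctan2(d[:, 1], d[:, 0]))
    turn_angles = np.abs(wrap_deg(np.diff(bearings)))
    return SegmentSeries(
        vertices=vertices,
        bearings=bearings,
        turn_angles=turn_angles,
        resample_length=float(resample_length),
    )


def directional_error(path: PathTable, goal_direction: float) -> float:
    """Absolute angle between the start-to-end chord and the goal direction, [0, 180]."""
    dx = path.x[-1] - path.x[0]
    dy = path.y[-1] - path.y[0]
    if dx == 0.0 and dy == 0.0:
        raise UndefinedAngleError("start and end coincide; chord direction undefined")
    bearing = np.rad2deg(np.arctan2(dy, dx))
    return float(abs(wrap_deg(bearing - goal_direction)))


def circular_mean_se(angles, ids=None) -> tuple[float, float]:
    """Circular mean and SE (circular SD / sqrt(n)) of angles in degrees.

    With ``ids`` given, angles are first averaged (circularly) within each id
    and the summary is taken across the id-level means — the mean +/- SE
    across individuals.
    """
    angles = np.asarray(angles, dtype=float)
    if ids is not None:
        ids = np.asarray(ids)
        angles = np.array([_circmean(angles[ids == uid]) for uid in pd_unique(ids)])
    if len(angles) < 2:
        raise ValueError("need at least 2 angles (or 2 ids)")
    rad = np.deg2rad(angles)
    resultant = np.mean(np.exp(1j * rad))
    if np.abs(resultant) < 1e-12:
        raise UndefinedAngleError("angles have zero resultant; circular mean undefined")
    mean = float(wrap_deg(np.rad2deg(stats.circmean(rad, high=np.pi, low=-np.pi))))
    sd = float(np.rad2deg(stats.circstd(rad, high=np.pi, low=-np.pi)))
    return mean, sd / np.sqrt(len(angles))


def _circmean(angles: np.ndarray) -> float:
    rad = np.deg2rad(np.asarray(angles, dtype=float))
    resultant = np.mean(np.exp(1j * rad))
    if np.abs(resultant) < 1e-12:
        raise UndefinedAngleError("angles have zero resultant; circular mean undefined")
    return float(wrap_deg(np.rad2deg(np.angle(resultant))))


def pd_unique(values):
    """First-appearance-ordered unique values."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def signed_rank_exact(values, alternative: str = "two_sided") -> float:
    """Exact one-sample Wilcoxon signed-rank p-value by full enumeration.

    Zeros are dropped before ranking (Wilcoxon's original treatment); ties
    receive average ranks.  The null distribution of the positive-rank sum is
    built over all 2^n sign assignments (via the rank generating polynomial,
    identical to explicit enumeration), so the p-value is exact even with
    ties.  Restricted to n <= 25 after zero removal.

    alternative: "greater" (median > 0), "less", or "two_sided"
    (2 * min one-sided, capped at 1).
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    v = v[v != 0]
    if len(v) == 0:
        raise ValueError("all values are zero; signed-rank test undefined")
    n = len(v)
    if n > 25:
        raise ValueError(f"exact enumeration restricted to n <= 25, got {n}")
    ranks = stats.rankdata(np.abs(v))
    # doubled ranks are integers even with average-rank ties
    r2 = np.rint(2 * ranks).astype(int)
    w2_obs = int(r2[v > 0].sum())
    # distribution of the doubled positive-rank sum over all sign assignments
    counts = np.zeros(int(r2.sum()) + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    total = 2.0 ** n
    p_greater = counts[w2_obs:].sum() / total
    p_less = counts[: w2_obs + 1].sum() / total
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    return float(min(1.0, 2.0 * min(p_greater, p_less)))
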