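"""Trajectory statistics for walking-through-a-crowd data.

Implements the measurement pipeline applied identically to experiment-style
and simulated trajectories:

* instantaneous speeds v(t) = ||p(t) - p(t-1)|| / dT from frame-indexed
  positions (backward difference, so speed t belongs to frame t);
* mean speeds over frame masks, with inside/outside-the-waiting-area frame
  classification (closed-rectangle convention for "inside"; "outside" is a
  free-flow measurement rectangle of the same width extending a margin
  before the entrance edge);
* time spent inside the waiting area (inside-frame count x dT);
* displacement metrics of the waiting crowd: end displacement
  ||p_end - p_first|| and maximum displacement max_t ||p_t - p_first||;
* the slow-down factor (outside over inside mean speed);
* a paired one-sided t-test for the speed drop inside the crowd;
* a Kolmogorov-Smirnov goodness-of-fit survey over a configurable list of
  candidate distribution families, retaining fits with p above a cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .scenario import Region

__all__ = [
    "SpeedSeries",
    "RegionStats",
    "DisplacementStats",
    "TTestResult",
    "instantaneous_speeds",
    "speeds_for",
    "mean_speed",
    "split_inside_outside",
    "duration_in_area",
    "displacement_stats",
    "slowdown_factor",
    "paired_onesided_ttest",
    "ks_fit_survey",
    "region_stats",
    "DEFAULT_OUTSIDE_MARGIN",
    "DEFAULT_KS_CANDIDATES",
]

logger = logging.getLogger(__name__)

#: depth (m) of the free-flow measurement rectangle before the entrance edge
DEFAULT_OUTSIDE_MARGIN = 1.5

#: scipy names of the default candidate families for the KS survey
DEFAULT_KS_CANDIDATES = (
    "norm",
    "lognorm",
    "gamma",
    "weibull_min",
    "beta",
    "expon",
    "chi",
)


@dataclass(frozen=True)
class SpeedSeries:
    """Per-frame-transition instantaneous speeds of one agent."""

    agent_id: int
    frame_interval: float
    speeds: np.ndarray  # length n_frames - 1; speeds[i] belongs to frame i+1


@dataclass(frozen=True)
class RegionStats:
    """Inside/outside mean speeds, frame counts and dwell time."""

    v_inside: float
    v_outside: float
    n_inside: int
    n_outside: int
    duration_in_area: float


@dataclass(frozen=True)
class DisplacementStats:
    """End (metric 1) and maximum (metric 2) displacement from the start."""

    end_displacement: float
    max_displacement: float


@dataclass(frozen=True)
class TTestResult:
    """One-sided lower paired t-test at significance level 0.05."""

    T: float
    N: int
    critical_value: float
    reject_H0: bool


def _positions(trajectory_of_one_agent) -> np.ndarray:
    pos = np.asarray(trajectory_of_one_agent, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("expected an (n_frames, 2) position array")
    return pos


def instantaneous_speeds(
    trajectory_of_one_agent, frame_interval: float, agent_id: int = 0
) -> SpeedSeries:
    """Speeds sqrt(dx^2 + dy^2) / dT over consecutive frame pairs."""
    pos = _positions(trajectory_of_one_agent)
    if len(pos) < 2:
        raise ValueError("need at least 2 frames to compute speeds")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    deltas = np.diff(pos, axis=0)
    speeds = np.sqrt((deltas**2).sum(axis=1)) / frame_interval
    return SpeedSeries(agent_id=agent_id, frame_interval=frame_interval, speeds=speeds)


def speeds_for(trajectory, agent_id: int) -> SpeedSeries:
    """Instantaneous speeds of one agent of a multi-agent trajectory.

    The agent's frames must be uniformly spaced (consecutive frame
    indices); gaps raise an explicit error instead of producing silently
    wrong speeds.
    """
    sub = trajectory.records[trajectory.records["pedestrianId"] == agent_id]
    if sub.empty:
        raise ValueError(f"agent {agent_id} not present in trajectory")
    sub = sub.sort_values("timeStep")
    steps = sub["timeStep"].to_numpy()
    if len(steps) >= 2 and not (np.diff(steps) == np.diff(steps)[0]).all():
        raise ValueError(f"non-uniform frame spacing for agent {agent_id}")
    return instantaneous_speeds(
        sub[["x", "y"]].to_numpy(dtype=float),
        trajectory.frame_interval,
        agent_id=agent_id,
    )


def mean_speed(series: SpeedSeries, frame_mask: Optional[np.ndarray] = None) -> float:
    """Arithmetic mean of instantaneous speeds over the masked frames.

    ``frame_mask`` is boolean per *frame* (length n_frames); the speed of
    frame t is the backward difference into t, so the first frame carries
    no speed.  An empty selection raises - it never returns NaN.
    """
    speeds = series.speeds
    if frame_mask is None:
        selected = speeds
    else:
        frame_mask = np.asarray(frame_mask, dtype=bool)
        if len(frame_mask) == len(speeds) + 1:
            selected = speeds[frame_mask[1:]]
        elif len(frame_mask) == len(speeds):
            selected = speeds[frame_mask]
        else:
            raise ValueError("frame_mask length does not match the series")
    if selected.size == 0:
        raise ValueError("mask selects no frames")
    return float(selected.mean())


def split_inside_outside(
    trajectory_of_one_agent,
    waiting_area: Region,
    outside_margin: float = DEFAULT_OUTSIDE_MARGIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify frames as inside the waiting area or in the free-flow strip.

    Inside: the closed waiting-area rectangle (boundary frames count as
    inside).  Outside: a rectangle of the same width extending
    ``outside_margin`` metres in -y before the entrance edge; frames on the
    shared edge belong to "inside" only.
    """
    pos = _positions(trajectory_of_one_agent)
    xmin, ymin, xmax, ymax = waiting_area.bounds
    x, y = pos[:, 0], pos[:, 1]
    inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
    outside = (
        (x >= xmin) & (x <= xmax) & (y >= ymin - outside_margin) & (y <= ymin)
        & ~inside
    )
    return inside, outside


def duration_in_area(
    trajectory_of_one_agent, waiting_area: Region, frame_interval: float
) -> float:
    """Dwell time in the waiting area: inside-frame count x frame interval."""
    inside, _ = split_inside_outside(trajectory_of_one_agent, waiting_area)
    return float(inside.sum()) * frame_interval


def displacement_stats(trajectory_of_one_agent) -> DisplacementStats:
    """End and maximum Euclidean displacement from the initial position."""
    pos = _positions(trajectory_of_one_agent)
    if len(pos) < 1:
        raise ValueError("need at least 1 frame")
    d = np.sqrt(((pos - pos[0]) ** 2).sum(axis=1))
    return DisplacementStats(
        end_displacement=float(d[-1]), max_displacement=float(d.max())
    )


def slowdown_factor(v_outside: float, v_inside: float) -> float:
    """Ratio of the free-flow (outside) to the in-crowd (inside) mean speed."""
    if v_inside <= 0:
        raise ValueError("v_inside must be > 0")
    return v_outside / v_inside


def paired_onesided_ttest(
    v_in: Sequence[float], v_out: Sequence[float], alpha: float = 0.05
) -> TTestResult:
    """Paired one-sided lower t-test on dv = v_in - v_out.

    H0: mean(dv) >= 0 (the crowd does not slow the walker down);
    H1: mean(dv) < 0.  T = sqrt(N) * mean(dv) / sd(dv) with the sample
    standard deviation; reject H0 iff T falls below the lower alpha
    quantile of the t distribution with N - 1 degrees of freedom.
    """
    v_in = np.asarray(v_in, dtype=float)
    v_out = np.asarray(v_out, dtype=float)
    if v_in.shape != v_out.shape or v_in.ndim != 1 or len(v_in) < 2:
        raise ValueError("v_in and v_out must be equal-length vectors (>= 2)")
    dv = v_in - v_out
    sd = float(dv.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance in the paired differences")
    n = len(dv)
    T = math.sqrt(n) * float(dv.mean()) / sd
    critical = float(sps.t.ppf(alpha, n - 1))
    return TTestResult(T=T, N=n, critical_value=critical, reject_H0=T < critical)


def ks_fit_survey(
    samples: Sequence[float],
    candidates: Iterable[str] = DEFAULT_KS_CANDIDATES,
    p_keep: float = 0.90,
) -> list[tuple[str, tuple[float, ...], float]]:
    """Maximum-likelihood fit + one-sample KS test per candidate family.

    Returns (family, fitted params, p-value) for the families whose KS
    p-value strictly exceeds ``p_keep``, sorted by descending p.  A family
    that fails to fit is skipped with a warning.  The p-values come from
    the asymptotic KS distribution without fitted-parameter correction.
    """
    samples = np.asarray(samples, dtype=float)
    candidates = list(candidates)
    if len(samples) < 20:
        raise ValueError("need at least 20 samples")
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    results: list[tuple[str, tuple[float, ...], float]] = []
    for name in candidates:
        dist = getattr(sps, name, None)
        if dist is None:
            logger.warning("unknown distribution family %r skipped", name)
            continue
        try:
            with np.errstate(all="ignore"):
                params = dist.fit(samples)
                p = float(sps.kstest(samples, name, args=params).pvalue)
        except Exception as exc:  # a family that cannot fit is not fatal
            logger.warning("fit of %r failed: %s", name, exc)
            continue
        if p > p_keep:
            results.append((name, tuple(float(v) for v in params), p))
    results.sort(key=lambda t: -t[2])
    return results


def region_stats(
    trajectory_of_one_agent,
    frame_interval: float,
    waiting_area: Region,
    outside_margin: float = DEFAULT_OUTSIDE_MARGIN,
) -> RegionStats:
    """Inside/outside mean speeds and dwell time for one agent.

    A region with no frames reports a mean speed of 0.0 and count 0.
    """
    pos = _positions(trajectory_of_one_agent)
    inside, outside = split_inside_outside(pos, waiting_area, outside_margin)
    series = instantaneous_speeds(pos, frame_interval)

    def masked_mean(mask: np.ndarray) -> float:
        return mean_speed(series, mask) if mask[1:].any() else 0.0

    return RegionStats(
        v_inside=masked_mean(inside),
        v_outside=masked_mean(outside),
        n_inside=int(inside.sum()),
        n_outside=int(outside.sum()),
        duration_in_area=float(inside.sum()) * frame_interval,
    )
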