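"""Locomotion layer: optimal-steps chooser, social-force baseline, speeds.

The primary locomotion rule is an optimal-steps-style chooser: each step the
agent evaluates a discretised disc of candidate footholds around itself
(16 directions x 4 radii plus staying put) and takes the admissible
candidate with the highest utility

    u(p) = - w_target * d_target(p)
           - w_agent * sum_j exp(-gap_j(p) / range_agent)
           - w_obstacle * sum_k exp(-gap_k(p) / range_obstacle)

where ``d_target`` is the Euclidean distance to the nearest point of the
target region (the corridor is convex, so this equals the geodesic),
``gap_j`` the surface gap to neighbour j and ``gap_k`` the gap to obstacle
k.  Admissibility is a hard constraint: a foothold is discarded when it
would overlap another agent's torso disc, an obstacle, or leave the domain.
The social-force baseline integrates a driving force towards the target
plus exponential repulsions; it reproduces the classic deadlock in front of
a dense stationary crowd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import shapely
import shapely.ops
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .psychology import AgentState
    from .scenario import Scenario

__all__ = [
    "UtilityWeights",
    "SocialForceParams",
    "StepProposal",
    "sample_free_flow_speed",
    "osm_next_position",
    "social_force_step",
]

#: admissibility slack for hard non-overlap (centre distance >= 2r - EPS)
EPS = 1e-9

N_DIRECTIONS = 16
RADIUS_FRACTIONS = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class UtilityWeights:
    """Weights of the optimal-steps utility.

    The *summed* agent repulsion gradient must stay below ``w_target``
    even with several torsos in contact, so that (a) a walker approaching a
    dense crowd closes in to contact distance instead of stalling out of
    swap reach, and (b) a fully blocked agent prefers standing still over
    retreating (dithering above the speed threshold would stop the
    cognition rule from ever firing).  With ~4 close neighbours that needs
    roughly 4 * w_agent / repulsion_range_agent < w_target.
    """

    w_target: float = 1.0
    w_agent: float = 0.1
    w_obstacle: float = 0.1
    repulsion_range_agent: float = 0.3
    repulsion_range_obstacle: float = 0.3

    def __post_init__(self) -> None:
        for name in ("w_target", "w_agent", "w_obstacle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.repulsion_range_agent <= 0 or self.repulsion_range_obstacle <= 0:
            raise ValueError("repulsion ranges must be > 0")


@dataclass(frozen=True)
class SocialForceParams:
    tau: float = 0.5  # relaxation time (s)
    a_agent: float = 5.0  # repulsion strength (m s^-2)
    b_agent: float = 0.3  # repulsion range (m)
    a_obstacle: float = 5.0
    b_obstacle: float = 0.1


@dataclass(frozen=True)
class StepProposal:
    """One candidate foothold and its utility."""

    position: tuple[float, float]
    utility: float


def sample_free_flow_speed(
    rng: np.random.Generator,
    mean: float = 1.34,
    sd: float = 0.26,
    lo: float = 0.5,
    hi: float = 2.2,
) -> float:
    """Draw a free-flow walking speed from a truncated normal (m/s).

    Defaults follow the empirical free-flow literature: mean 1.34 m/s,
    s.d. 0.26 m/s, truncated to [0.5, 2.2] m/s.
    """
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _candidate_points(
    position: np.ndarray, step_radius: float, target_azimuth: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Candidate footholds on the step disc.

    One spoke of the candidate fan is aligned with the target azimuth so
    that unobstructed walking is exactly straight.  Returns (points, angles
    relative to the target direction, radii); staying put is handled
    separately by the caller.
    """
    rel = 2.0 * np.pi * np.arange(N_DIRECTIONS) / N_DIRECTIONS
    rel = np.where(rel > np.pi, rel - 2.0 * np.pi, rel)  # signed, target-relative
    angles = target_azimuth + rel
    radii = step_radius * np.asarray(RADIUS_FRACTIONS)
    pts = (
        position[None, None, :]
        + radii[None, :, None]
        * np.stack([np.cos(angles), np.sin(angles)], axis=-1)[:, None, :]
    )
    n = N_DIRECTIONS * len(RADIUS_FRACTIONS)
    rel_grid = np.repeat(np.abs(rel), len(RADIUS_FRACTIONS))
    rad_grid = np.tile(radii, N_DIRECTIONS)
    return pts.reshape(n, 2), rel_grid, rad_grid


def _utilities(
    pts: np.ndarray,
    scenario: "Scenario",
    target_polygon,
    neighbour_positions: np.ndarray,
    weights: UtilityWeights,
) -> np.ndarray:
    br = scenario.params.body_radius
    shp_pts = shapely.points(pts)
    u = -weights.w_target * shapely.distance(target_polygon, shp_pts)
    if len(neighbour_positions):
        d = np.sqrt(
            ((pts[:, None, :] - neighbour_positions[None, :, :]) ** 2).sum(-1)
        )
        gaps = np.clip(d - 2.0 * br, 0.0, None)
        u -= weights.w_agent * np.exp(-gaps / weights.repulsion_range_agent).sum(1)
    for obs in scenario.obstacles:
        gaps = np.clip(shapely.distance(obs.polygon, shp_pts) - br, 0.0, None)
        u -= weights.w_obstacle * np.exp(-gaps / weights.repulsion_range_obstacle)
    return np.asarray(u, dtype=float)


def _admissible(
    pts: np.ndarray,
    scenario: "Scenario",
    neighbour_positions: np.ndarray,
) -> np.ndarray:
    br = scenario.params.body_radius
    xmin, ymin, xmax, ymax = scenario.domain_bounds.bounds
    ok = (
        (pts[:, 0] >= xmin + br - EPS)
        & (pts[:, 0] <= xmax - br + EPS)
        & (pts[:, 1] >= ymin + br - EPS)
        & (pts[:, 1] <= ymax - br + EPS)
    )
    if len(neighbour_positions):
        d = np.sqrt(
            ((pts[:, None, :] - neighbour_positions[None, :, :]) ** 2).sum(-1)
        )
        ok &= (d >= 2.0 * br - EPS).all(axis=1)
    if scenario.obstacles:
        shp_pts = shapely.points(pts)
        for obs in scenario.obstacles:
            ok &= shapely.distance(obs.polygon, shp_pts) >= br - EPS
    return ok


def osm_next_position(
    agent: "AgentState",
    neighbours: Sequence["AgentState"],
    scenario: "Scenario",
    weights: Optional[UtilityWeights] = None,
    dt: Optional[float] = None,
) -> np.ndarray:
    """Optimal-steps update: the utility-maximising admissible foothold.

    Staying put is always a candidate and wins ties; among equally good
    moves the one with the smallest angle to the target, then the smallest
    radius, is chosen.  With no admissible improving move the agent stays
    (recorded speed 0) - never an exception.
    """
    weights = weights or UtilityWeights()
    dt = scenario.params.dt if dt is None else dt
    position = np.asarray(agent.position, dtype=float)
    target_polygon = scenario.target.polygon

    to_target = shapely.ops.nearest_points(
        shapely.points(position), target_polygon
    )[1]
    dx, dy = to_target.x - position[0], to_target.y - position[1]
    if dx == 0.0 and dy == 0.0:  # already at/inside the target
        return position
    azimuth = math.atan2(dy, dx)

    step_radius = agent.free_flow_speed * dt
    pts, rel_angles, radii = _candidate_points(position, step_radius, azimuth)
    neighbour_positions = np.asarray(
        [np.asarray(n.position, dtype=float) for n in neighbours]
    ).reshape(-1, 2)

    ok = _admissible(pts, scenario, neighbour_positions)
    stay_utility = float(
        _utilities(position[None, :], scenario, target_polygon,
                   neighbour_positions, weights)[0]
    )
    if not ok.any():
        return position
    pts, rel_angles, radii = pts[ok], rel_angles[ok], radii[ok]
    u = _utilities(pts, scenario, target_polygon, neighbour_positions, weights)

    # moves must strictly beat staying put
    better = u > stay_utility + 1e-12
    if not better.any():
        return position
    pts, rel_angles, radii, u = pts[better], rel_angles[better], radii[better], u[better]
    order = np.lexsort((radii, rel_angles, -u))
    return pts[order[0]].copy()


def social_force_step(
    agent: "AgentState",
    neighbours: Sequence["AgentState"],
    scenario: "Scenario",
    dt: Optional[float] = None,
    params: Optional[SocialForceParams] = None,
) -> np.ndarray:
    """Social-force baseline: driving force plus exponential repulsions.

    Integrates velocity explicitly over dt and clamps the displacement so
    hard non-overlap still holds.  Mutates ``agent.velocity``.
    """
    params = params or SocialForceParams()
    dt = scenario.params.dt if dt is None else dt
    br = scenario.params.body_radius
    position = np.asarray(agent.position, dtype=float)
    velocity = np.asarray(agent.velocity, dtype=float)

    target_polygon = scenario.target.polygon
    nearest = shapely.ops.nearest_points(shapely.points(position), target_polygon)[1]
    e = np.array([nearest.x - position[0], nearest.y - position[1]])
    norm = np.linalg.norm(e)
    e = e / norm if norm > 0 else np.zeros(2)

    accel = (agent.free_flow_speed * e - velocity) / params.tau
    for other in neighbours:
        diff = position - np.asarray(other.position, dtype=float)
        d = np.linalg.norm(diff)
        if d <= 0:
            continue
        gap = max(d - 2.0 * br, 0.0)
        accel += params.a_agent * math.exp(-gap / params.b_agent) * diff / d
    for obs in scenario.obstacles:
        near = shapely.ops.nearest_points(shapely.points(position), obs.polygon)[1]
        diff = position - np.array([near.x, near.y])
        d = np.linalg.norm(diff)
        if d <= 0:
            continue
        gap = max(d - br, 0.0)
        accel += params.a_obstacle * math.exp(-gap / params.b_obstacle) * diff / d

    velocity = velocity + accel * dt
    speed = np.linalg.norm(velocity)
    if speed > agent.free_flow_speed:
        velocity = velocity * (agent.free_flow_speed / speed)

    neighbour_positions = np.asarray(
        [np.asarray(n.position, dtype=float) for n in neighbours]
    ).reshape(-1, 2)
    displacement = velocity * dt
    scale = 1.0
    for _ in range(24):
        trial = position + scale * displacement
        if _admissible(trial[None, :], scenario, neighbour_positions)[0]:
            break
        scale *= 0.5
    else:
        scale = 0.0
    new_position = position + scale * displacement
    agent.velocity = (new_position - position) / dt
    return new_position
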