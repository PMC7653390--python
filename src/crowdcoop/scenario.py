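"""World geometry, agent roster and model parameters.

A :class:`Scenario` is the static world of a simulation: a rectangular
corridor, a delimited waiting area occupied by a stationary crowd, a source
region where the walking agent starts, a target region it tries to reach,
and obstacle strips (tables) flanking the waiting area so the walker cannot
slip around the crowd.

:func:`build_reenactment_scenario` constructs the crossing scenario with the
published experiment dimensions: a 1.55 m x 1.70 m waiting area (2.64 m^2
rounded) holding 13 waiting agents, crossed by one walking agent along +y,
at a crossing density of 14 agents / 2.64 m^2 ~ 5.30 ped/m^2.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from shapely.geometry import Point, Polygon

__all__ = [
    "Region",
    "AgentSpec",
    "ModelParams",
    "Scenario",
    "ScenarioError",
    "CapacityError",
    "build_reenactment_scenario",
    "place_waiting_crowd",
    "load_scenario",
    "save_scenario",
]


class ScenarioError(ValueError):
    """Invalid scenario geometry or parameters."""


class CapacityError(ScenarioError):
    """Requested crowd does not fit into the given area without overlaps."""


@dataclass(frozen=True)
class Region:
    """A planar region in metres: an axis-aligned rectangle or a polygon."""

    kind: str  # "rectangle" | "polygon"
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "polygon"):
            raise ScenarioError(f"unknown region kind {self.kind!r}")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )
        if self.polygon.area <= 0.0:
            raise ScenarioError("degenerate region (area must be > 0)")
        if self.kind == "rectangle":
            xs = {v[0] for v in self.vertices}
            ys = {v[1] for v in self.vertices}
            if len(self.vertices) != 4 or len(xs) != 2 or len(ys) != 2:
                raise ScenarioError("rectangle must be axis-aligned with 4 vertices")

    @classmethod
    def rectangle(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "Region":
        return cls(
            "rectangle", ((xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax))
        )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    def contains(self, point: Sequence[float]) -> bool:
        """Closed-set containment: boundary points are inside."""
        if self.kind == "rectangle":
            xmin, ymin, xmax, ymax = self.bounds
            return bool(xmin <= point[0] <= xmax and ymin <= point[1] <= ymax)
        return bool(self.polygon.covers(Point(point[0], point[1])))

    def distance(self, point: Sequence[float]) -> float:
        """Euclidean distance from a point to the nearest point of the region."""
        return self.polygon.distance(Point(point[0], point[1]))


@dataclass(frozen=True)
class AgentSpec:
    """Initial description of one agent.

    ``free_flow_speed`` may be ``None`` for a walker, meaning the speed is
    drawn from the free-flow distribution at the start of each run.
    """

    id: int
    initial_position: tuple[float, float]
    role: str  # "walker" | "waiter"
    free_flow_speed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ("walker", "waiter"):
            raise ScenarioError(f"unknown role {self.role!r}")
        if self.free_flow_speed is not None and self.free_flow_speed <= 0:
            raise ScenarioError("free_flow_speed must be > 0")


@dataclass(frozen=True)
class ModelParams:
    """Simulation parameters.

    dt
        Simulation step interval in seconds. One step corresponds to one
        stride of the optimal-steps chooser, so dt is the stride duration
        (~0.4 s at typical walking speed).
    r
        Perception / swap-partner search radius in metres. Kept near one
        stride length so position exchanges happen between bodily adjacent
        agents.
    n_history
        Number of past steps whose speeds the cognition rule inspects.
    v_threshold
        Speed (m/s) below which an agent counts as unable to move; if the
        last ``n_history`` speeds all fall below it the agent switches its
        self-category to cooperative.
    body_radius
        Torso radius (m); hard non-overlap keeps centre distances at
        >= 2 * body_radius.
    v_free_mean, v_free_sd, v_free_min, v_free_max
        Truncated-normal free-flow speed distribution (m/s).
    t_max
        Simulation horizon in seconds; a run that exceeds it counts as a
        failed crossing, not an error.
    """

    dt: float = 0.4
    r: float = 0.5
    n_history: int = 3
    v_threshold: float = 0.05
    body_radius: float = 0.195
    v_free_mean: float = 1.34
    v_free_sd: float = 0.26
    v_free_min: float = 0.5
    v_free_max: float = 2.2
    t_max: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "dt": self.dt,
            "r": self.r,
            "v_threshold": self.v_threshold,
            "body_radius": self.body_radius,
            "v_free_mean": self.v_free_mean,
            "v_free_sd": self.v_free_sd,
            "v_free_min": self.v_free_min,
            "v_free_max": self.v_free_max,
            "t_max": self.t_max,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ScenarioError(f"{name} must be > 0 (got {value})")
        if self.n_history < 1:
            raise ScenarioError("n_history must be >= 1")
        if not self.v_threshold < self.v_free_mean:
            raise ScenarioError("v_threshold must be below v_free_mean")
        if not self.v_free_min < self.v_free_max:
            raise ScenarioError("v_free_min must be below v_free_max")


@dataclass(frozen=True)
class Scenario:
    """Static world: geometry, agent roster and parameters."""

    domain_bounds: Region
    waiting_area: Region
    source: Region
    target: Region
    obstacles: tuple[Region, ...]
    walking_agent_spec: AgentSpec
    waiting_agent_specs: tuple[AgentSpec, ...]
    params: ModelParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "obstacles", tuple(self.obstacles))
        object.__setattr__(
            self, "waiting_agent_specs", tuple(self.waiting_agent_specs)
        )
        self._validate()

    def _validate(self) -> None:
        dom = self.domain_bounds.polygon
        for name, region in (
            ("waiting_area", self.waiting_area),
            ("source", self.source),
            ("target", self.target),
        ):
            if not dom.covers(region.polygon):
                raise ScenarioError(f"{name} must lie inside domain_bounds")
        # walking axis is +y: source below the waiting area, target above
        if not (
            self.source.bounds[3] <= self.waiting_area.bounds[1]
            and self.target.bounds[1] >= self.waiting_area.bounds[3]
        ):
            raise ScenarioError(
                "source and target must flank the waiting area along the y axis"
            )
        ids = [self.walking_agent_spec.id] + [s.id for s in self.waiting_agent_specs]
        if len(ids) != len(set(ids)):
            raise ScenarioError("agent ids must be unique")
        br = self.params.body_radius
        for spec in self.all_agent_specs():
            p = Point(spec.initial_position)
            for obs in self.obstacles:
                if obs.polygon.distance(p) < br:
                    raise ScenarioError(
                        f"agent {spec.id} placed overlapping an obstacle"
                    )

    def all_agent_specs(self) -> tuple[AgentSpec, ...]:
        return (self.walking_agent_spec,) + self.waiting_agent_specs


# --- re-enactment geometry -------------------------------------------------
#
# Corridor 4.0 m x 7.0 m, origin at the bottom-left, walking direction +y.
# The waiting area (1.55 m x 1.70 m) sits centred in x with its entrance
# edge at y = 2.65; tables close the corridor on both sides of the area.

CORRIDOR_WIDTH = 4.0
CORRIDOR_HEIGHT = 7.0
WAITING_WIDTH = 1.55
WAITING_HEIGHT = 1.70
WAITING_ENTRANCE_Y = 2.65
N_WAITERS = 13

#: standoff between the entrance edge and the contact point of the front row,
#: so that a walker halted by the crowd has already entered the area
FRONT_STANDOFF = 0.15
#: clearance between a waiter's torso disc and the flanking tables
TABLE_CLEARANCE = 0.02


def _reenactment_crowd_layout(params: ModelParams) -> list[tuple[float, float]]:
    """Staggered 3-2-3-2-3 lattice for the 13-strong waiting crowd.

    Rows run front (entrance side) to back; the front row stands one body
    diameter plus a small standoff behind the entrance edge so that the
    walker, halted at contact distance, is already inside the area.
    """
    br = params.body_radius
    xmin = (CORRIDOR_WIDTH - WAITING_WIDTH) / 2.0
    xmax = xmin + WAITING_WIDTH
    ymin = WAITING_ENTRANCE_Y
    ymax = ymin + WAITING_HEIGHT

    col_lo = xmin + br + TABLE_CLEARANCE
    col_hi = xmax - br - TABLE_CLEARANCE
    col_mid = (col_lo + col_hi) / 2.0
    full_cols = (col_lo, col_mid, col_hi)
    half_cols = ((col_lo + col_mid) / 2.0, (col_mid + col_hi) / 2.0)

    y_front = ymin + 2.0 * br + FRONT_STANDOFF
    y_back = ymax - 0.01
    if y_back <= y_front:
        raise CapacityError("waiting area too shallow for the crowd lattice")
    dy = (y_back - y_front) / 4.0

    points: list[tuple[float, float]] = []
    for i in range(5):
        cols = full_cols if i % 2 == 0 else half_cols
        y = y_front + i * dy
        points.extend((x, y) for x in cols)

    pts = np.asarray(points)
    dmin = _min_pairwise_distance(pts)
    if dmin < 2.0 * br:
        raise CapacityError(
            f"body_radius {br} m makes {N_WAITERS} non-overlapping waiters "
            f"impossible (min spacing {dmin:.3f} m < {2 * br:.3f} m)"
        )
    return points


def _min_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return math.inf
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    return float(d[np.triu_indices(len(points), k=1)].min())


def place_waiting_crowd(
    n: int, area: Region, body_radius: float
) -> list[tuple[float, float]]:
    """Deterministic centred grid of ``n`` points inside ``area``.

    Row-major layout with a centred final row; pairwise distances stay at
    >= 2 * body_radius and every point lies strictly inside the area.
    Raises :class:`CapacityError` when no grid satisfies the spacing.
    """
    if n < 0:
        raise ScenarioError("n must be >= 0")
    if n == 0:
        return []
    xmin, ymin, xmax, ymax = area.bounds
    if n == 1:
        return [area.centroid]

    inset = 0.01
    width = xmax - xmin - 2 * inset
    height = ymax - ymin - 2 * inset

    best: Optional[list[tuple[float, float]]] = None
    best_dmin = -math.inf
    for ncols in range(1, n + 1):
        nrows = math.ceil(n / ncols)
        sx = width / (ncols - 1) if ncols > 1 else 0.0
        sy = height / (nrows - 1) if nrows > 1 else 0.0
        x0 = xmin + inset if ncols > 1 else (xmin + xmax) / 2.0
        y0 = ymin + inset if nrows > 1 else (ymin + ymax) / 2.0
        pts: list[tuple[float, float]] = []
        for row in range(nrows):
            in_row = min(ncols, n - row * ncols)
            # centre a short final row
            offset = (ncols - in_row) * sx / 2.0
            for col in range(in_row):
                pts.append((x0 + offset + col * sx, y0 + row * sy))
        candidate = pts[:n]
        if not all(area.contains(p) for p in candidate):
            continue
        dmin = _min_pairwise_distance(np.asarray(candidate))
        if dmin > best_dmin:
            best_dmin = dmin
            best = candidate
    if best is None or best_dmin < 2.0 * body_radius:
        raise CapacityError(
            f"cannot place {n} agents with body radius {body_radius} m "
            f"in area {area.bounds} (best spacing {best_dmin:.3f} m)"
        )
    return best


def build_reenactment_scenario(params: Optional[ModelParams] = None) -> Scenario:
    """Build the crossing scenario with the published experiment dimensions.

    13 waiting agents stand in a 1.55 m x 1.70 m delimited area on a
    deterministic staggered lattice; one walking agent starts in the source
    region below and aims for the target region above; tables seal the
    corridor left and right of the waiting area.
    """
    params = params or ModelParams()
    xmin = (CORRIDOR_WIDTH - WAITING_WIDTH) / 2.0
    xmax = xmin + WAITING_WIDTH
    ymin = WAITING_ENTRANCE_Y
    ymax = ymin + WAITING_HEIGHT

    domain = Region.rectangle(0.0, 0.0, CORRIDOR_WIDTH, CORRIDOR_HEIGHT)
    waiting = Region.rectangle(xmin, ymin, xmax, ymax)
    source = Region.rectangle(xmin, 0.1, xmax, 0.9)
    target = Region.rectangle(xmin, 6.1, xmax, 6.9)
    tables = (
        Region.rectangle(0.0, ymin, xmin, ymax),
        Region.rectangle(xmax, ymin, CORRIDOR_WIDTH, ymax),
    )

    crowd = _reenactment_crowd_layout(params)
    # ids: walker first, then waiters front-to-back, left-to-right
    walker = AgentSpec(
        id=1,
        initial_position=(CORRIDOR_WIDTH / 2.0, source.bounds[1]),
        role="walker",
        free_flow_speed=None,
    )
    waiters = tuple(
        AgentSpec(
            id=i + 2,
            initial_position=p,
            role="waiter",
            free_flow_speed=params.v_free_mean,
        )
        for i, p in enumerate(crowd)
    )
    return Scenario(
        domain_bounds=domain,
        waiting_area=waiting,
        source=source,
        target=target,
        obstacles=tables,
        walking_agent_spec=walker,
        waiting_agent_specs=waiters,
        params=params,
    )


# --- config file round trip ------------------------------------------------


def _region_to_dict(region: Region) -> dict:
    return {"kind": region.kind, "vertices": [list(v) for v in region.vertices]}


def _region_from_dict(d: dict) -> Region:
    return Region(d["kind"], tuple((v[0], v[1]) for v in d["vertices"]))


def _spec_to_dict(spec: AgentSpec) -> dict:
    return {
        "id": spec.id,
        "initial_position": list(spec.initial_position),
        "role": spec.role,
        "free_flow_speed": spec.free_flow_speed,
    }


def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "domain_bounds": _region_to_dict(scenario.domain_bounds),
        "waiting_area": _region_to_dict(scenario.waiting_area),
        "source": _region_to_dict(scenario.source),
        "target": _region_to_dict(scenario.target),
        "obstacles": [_region_to_dict(o) for o in scenario.obstacles],
        "walking_agent": _spec_to_dict(scenario.walking_agent_spec),
        "waiting_agents": [_spec_to_dict(s) for s in scenario.waiting_agent_specs],
        "params": dataclasses.asdict(scenario.params),
    }


def scenario_from_dict(d: dict) -> Scenario:
    def spec(s: dict) -> AgentSpec:
        return AgentSpec(
            id=int(s["id"]),
            initial_position=(s["initial_position"][0], s["initial_position"][1]),
            role=s["role"],
            free_flow_speed=s.get("free_flow_speed"),
        )

    return Scenario(
        domain_bounds=_region_from_dict(d["domain_bounds"]),
        waiting_area=_region_from_dict(d["waiting_area"]),
        source=_region_from_dict(d["source"]),
        target=_region_from_dict(d["target"]),
        obstacles=tuple(_region_from_dict(o) for o in d.get("obstacles", [])),
        walking_agent_spec=spec(d["walking_agent"]),
        waiting_agent_specs=tuple(spec(s) for s in d.get("waiting_agents", [])),
        params=ModelParams(**d.get("params", {})),
    )


def save_scenario(path: str | Path, scenario: Scenario) -> None:
    """Write a scenario config (.json, .yaml or .yml by extension)."""
    path = Path(path)
    d = scenario_to_dict(scenario)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario config written by :func:`save_scenario`."""
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scenario_from_dict(d)
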