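"""Psychology layer: perception, cognition and the cooperative swap.

Three sequential sub-layers run each simulation step, each consuming only
the output of the layer above it:

perception
    An agent perceives the other agents within a search radius ``r``
    (closed ball, sorted by distance then id).
cognition
    An agent that could not move for the last ``n_history`` steps (every
    recorded speed below ``v_threshold``) changes its self-category from
    target-oriented to cooperative; once its recent mean speed is back
    above the threshold it reverts (walker -> target-oriented, waiter ->
    wait).  The rule reads only the agent's own speed history and its
    percept - no global state.
behaviour
    A cooperative agent with a target searches its percept for a
    cooperative neighbour strictly closer to the target and swaps positions
    with it within a single step; both partners carry a one-step swap
    cooldown.

The perception and cognition rules are pluggable single-method strategies
(:class:`PerceptionModel`, :class:`CognitionModel`); the shipped
implementations are :func:`simple_perception` (pure radius filter - there
are no external stimuli in the crossing scenario) and
:func:`cooperative_cognition`.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Protocol, Sequence

import numpy as np

from .scenario import ModelParams, Region

__all__ = [
    "SelfCategory",
    "AgentState",
    "Percept",
    "SwapRejected",
    "perceive",
    "update_cognition",
    "find_swap_candidate",
    "execute_swap",
    "PerceptionModel",
    "CognitionModel",
    "simple_perception",
    "cooperative_cognition",
]


class SelfCategory(Enum):
    """An agent's active social identity, governing its behaviour."""

    TARGET_ORIENTED = "TARGET_ORIENTED"
    COOPERATIVE = "COOPERATIVE"
    WAIT = "WAIT"


@dataclass
class AgentState:
    """Dynamic state of one agent."""

    id: int
    position: np.ndarray
    free_flow_speed: float
    role: str  # "walker" | "waiter"
    self_category: SelfCategory = SelfCategory.TARGET_ORIENTED
    speed_history: deque = field(default_factory=lambda: deque(maxlen=64))
    target_region_id: Optional[str] = None
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    swap_cooldown: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)

    @property
    def has_target(self) -> bool:
        return self.target_region_id is not None

    def recent_speeds(self, n: int) -> list[float]:
        h = list(self.speed_history)
        return h[-n:]


@dataclass(frozen=True)
class Percept:
    """Neighbour set within the search radius, sorted by distance then id."""

    observer_id: int
    neighbour_ids: tuple[int, ...]
    neighbour_positions: tuple[tuple[float, float], ...]


class SwapRejected(ValueError):
    """Swap precondition violated; no state was changed."""


def perceive(agent: AgentState, all_agents: Sequence[AgentState], r: float) -> Percept:
    """Perception sub-layer: agents within centre distance <= r (closed ball).

    The observer itself is excluded; results sorted by distance, ties by id.
    """
    if r <= 0:
        raise ValueError("perception radius r must be > 0")
    found: list[tuple[float, int, tuple[float, float]]] = []
    p = np.asarray(agent.position, dtype=float)
    for other in all_agents:
        if other.id == agent.id:
            continue
        d = float(np.linalg.norm(np.asarray(other.position, dtype=float) - p))
        if d <= r:
            found.append((d, other.id, (other.position[0], other.position[1])))
    found.sort(key=lambda t: (t[0], t[1]))
    return Percept(
        observer_id=agent.id,
        neighbour_ids=tuple(t[1] for t in found),
        neighbour_positions=tuple(t[2] for t in found),
    )


def update_cognition(
    agent: AgentState, percept: Percept, params: ModelParams
) -> SelfCategory:
    """Cognition sub-layer: self-category from the recent speed history.

    * every one of the last ``n_history`` speeds below ``v_threshold``
      -> COOPERATIVE ("the agent cannot move anymore");
    * mean of the last ``n_history`` speeds at or above the threshold
      -> back to TARGET_ORIENTED (walker) / WAIT (waiter);
    * shorter history or anything in between -> category unchanged.
    """
    history = agent.recent_speeds(params.n_history)
    if len(history) < params.n_history:
        return agent.self_category
    if all(s < params.v_threshold for s in history):
        return SelfCategory.COOPERATIVE
    if sum(history) / len(history) >= params.v_threshold:
        return (
            SelfCategory.TARGET_ORIENTED
            if agent.role == "walker"
            else SelfCategory.WAIT
        )
    return agent.self_category


def find_swap_candidate(
    agent: AgentState,
    percept: Percept,
    all_agents: Sequence[AgentState],
    target: Region,
) -> Optional[int]:
    """Pick the swap partner: the perceived cooperative neighbour strictly
    closer to the target that minimises the distance to the target; ties go
    to the smaller id.  Returns ``None`` when no such neighbour exists."""
    if agent.self_category is not SelfCategory.COOPERATIVE:
        return None
    by_id = {a.id: a for a in all_agents}
    d_self = target.distance(agent.position)
    best: Optional[tuple[float, int]] = None
    for nid in percept.neighbour_ids:
        other = by_id.get(nid)
        if other is None or other.self_category is not SelfCategory.COOPERATIVE:
            continue
        d = target.distance(other.position)
        if d < d_self and (best is None or (d, nid) < best):
            best = (d, nid)
    return best[1] if best is not None else None


def execute_swap(
    a: AgentState, b: AgentState, r: float = math.inf
) -> tuple[AgentState, AgentState]:
    """Exchange the positions of two cooperative agents within one step.

    Both agents must be COOPERATIVE and within mutual distance ``r``; all
    other fields are preserved and both receive a one-step swap cooldown.
    Raises :class:`SwapRejected` (leaving both untouched) otherwise.
    """
    if (
        a.self_category is not SelfCategory.COOPERATIVE
        or b.self_category is not SelfCategory.COOPERATIVE
    ):
        raise SwapRejected("both agents must be cooperative to swap")
    if float(np.linalg.norm(a.position - b.position)) > r:
        raise SwapRejected("swap partners out of reach")
    a.position, b.position = b.position.copy(), a.position.copy()
    a.swap_cooldown = 1
    b.swap_cooldown = 1
    return a, b


# --- pluggable strategy interfaces ----------------------------------------


class PerceptionModel(Protocol):
    """Single-method perception strategy."""

    def update(
        self, agent: AgentState, all_agents: Sequence[AgentState], params: ModelParams
    ) -> Percept: ...


class CognitionModel(Protocol):
    """Single-method cognition strategy."""

    def update(
        self, agent: AgentState, percept: Percept, params: ModelParams
    ) -> SelfCategory: ...


class simple_perception:
    """Radius filter; no external stimuli."""

    def update(
        self, agent: AgentState, all_agents: Sequence[AgentState], params: ModelParams
    ) -> Percept:
        return perceive(agent, all_agents, params.r)


class cooperative_cognition:
    """Speed-history self-category switching."""

    def update(
        self, agent: AgentState, percept: Percept, params: ModelParams
    ) -> SelfCategory:
        return update_cognition(agent, percept, params)
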