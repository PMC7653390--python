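"""Simulation loop: perception -> cognition -> behaviour, plus batch mode.

Each step every agent (visited in a seeded random order to avoid
simultaneous-swap conflicts) first updates its percept and self-category,
then acts: target-oriented agents take a locomotion step, waiting agents
stand still, cooperative agents try to swap positions with a suitable
partner and fall back to locomotion.  Speed histories are fed from the
realised displacement of each step, so the cognition rule sees exactly the
speeds that the output trajectory implies.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis
from .locomotion import (
    SocialForceParams,
    UtilityWeights,
    osm_next_position,
    sample_free_flow_speed,
    social_force_step,
)
from .psychology import (
    AgentState,
    SelfCategory,
    execute_swap,
    find_swap_candidate,
    perceive,
    update_cognition,
)
from .scenario import Scenario

__all__ = ["SimulationState", "Trajectory", "RunSummary", "run_simulation", "run_batch"]

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["timeStep", "pedestrianId", "x", "y", "selfCategory"]


@dataclass
class Trajectory:
    """Frame-indexed positions of all agents at a fixed frame interval.

    ``records`` holds one row per agent per frame, sorted by
    (timeStep, pedestrianId); frame indices start at 1 (the initial state).
    """

    frame_interval: float
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in TRAJECTORY_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory records missing columns {missing}")
        if "selfCategory" not in df.columns:
            df = df.assign(selfCategory=None)
        df = df.sort_values(["timeStep", "pedestrianId"], kind="mergesort")
        if df.duplicated(["timeStep", "pedestrianId"]).any():
            raise ValueError("duplicate (timeStep, pedestrianId) record")
        self.records = df.reset_index(drop=True)[TRAJECTORY_COLUMNS]

    @property
    def agent_ids(self) -> list[int]:
        return sorted(self.records["pedestrianId"].unique().tolist())

    @property
    def n_frames(self) -> int:
        return self.records["timeStep"].nunique()

    def positions_of(self, agent_id: int) -> np.ndarray:
        """(n_frames, 2) positions of one agent in frame order."""
        sub = self.records[self.records["pedestrianId"] == agent_id]
        sub = sub.sort_values("timeStep")
        return sub[["x", "y"]].to_numpy(dtype=float)

    def categories_of(self, agent_id: int) -> list:
        sub = self.records[self.records["pedestrianId"] == agent_id]
        return sub.sort_values("timeStep")["selfCategory"].tolist()


@dataclass(frozen=True)
class RunSummary:
    """Per-run acceptance surface: crossing success and walker statistics."""

    crossed: bool
    duration_in_area: float
    mean_speed_inside: float
    mean_speed_outside: float
    seed: int


@dataclass
class SimulationState:
    clock: float
    step_index: int
    agents: list[AgentState]
    rng: np.random.Generator


def _build_agents(scenario: Scenario, rng: np.random.Generator) -> list[AgentState]:
    params = scenario.params
    agents: list[AgentState] = []
    for spec in scenario.all_agent_specs():
        speed = spec.free_flow_speed
        if speed is None:
            speed = sample_free_flow_speed(
                rng,
                mean=params.v_free_mean,
                sd=params.v_free_sd,
                lo=params.v_free_min,
                hi=params.v_free_max,
            )
        agents.append(
            AgentState(
                id=spec.id,
                position=np.asarray(spec.initial_position, dtype=float),
                free_flow_speed=speed,
                role=spec.role,
                self_category=SelfCategory.TARGET_ORIENTED,
                speed_history=deque(maxlen=params.n_history),
                target_region_id="target" if spec.role == "walker" else None,
            )
        )
    return agents


def run_simulation(
    scenario: Scenario,
    seed: int,
    psychology: bool = True,
    locomotion: str = "osm",
    weights: Optional[UtilityWeights] = None,
    sf_params: Optional[SocialForceParams] = None,
    return_state: bool = False,
):
    """Run one crossing simulation until the walker reaches the target or
    the horizon ``t_max`` elapses (then ``crossed`` is False, no exception).

    Deterministic for a fixed seed.  ``psychology=False`` disables the
    perception/cognition/swap layer, leaving pure locomotion - the classic
    deadlock baseline.
    """
    if locomotion not in ("osm", "social-force"):
        raise ValueError("locomotion must be 'osm' or 'social-force'")
    params = scenario.params
    weights = weights or UtilityWeights()
    rng = np.random.default_rng(seed)
    agents = _build_agents(scenario, rng)
    by_id = {a.id: a for a in agents}
    walker = next(a for a in agents if a.role == "walker")

    rows: list[tuple] = []

    def record(step: int) -> None:
        for a in agents:
            rows.append(
                (step, a.id, float(a.position[0]), float(a.position[1]),
                 a.self_category.value)
            )

    record(1)
    crossed = scenario.target.contains(walker.position)
    n_steps = int(round(params.t_max / params.dt))
    state = SimulationState(clock=0.0, step_index=0, agents=agents, rng=rng)

    for step in range(1, n_steps + 1):
        prev = {a.id: a.position.copy() for a in agents}
        order = rng.permutation(len(agents))
        for idx in order:
            agent = agents[idx]
            percept = None
            if psychology:
                percept = perceive(agent, agents, params.r)
                new_cat = update_cognition(agent, percept, params)
                if new_cat is not agent.self_category:
                    logger.debug(
                        "step %d: agent %d %s -> %s",
                        step, agent.id, agent.self_category.value, new_cat.value,
                    )
                agent.self_category = new_cat
            if agent.swap_cooldown > 0:
                continue  # already exchanged this step / cooling down
            if not agent.has_target or agent.self_category is SelfCategory.WAIT:
                continue  # the waiting crowd does not move at all
            if psychology and agent.self_category is SelfCategory.COOPERATIVE:
                cand_id = find_swap_candidate(agent, percept, agents, scenario.target)
                if cand_id is not None and by_id[cand_id].swap_cooldown == 0:
                    execute_swap(agent, by_id[cand_id], r=params.r)
                    logger.debug(
                        "step %d: swap %d <-> %d", step, agent.id, cand_id
                    )
                    continue
            neighbours = [a for a in agents if a.id != agent.id]
            if locomotion == "osm":
                agent.position = osm_next_position(
                    agent, neighbours, scenario, weights, params.dt
                )
            else:
                agent.position = social_force_step(
                    agent, neighbours, scenario, params.dt, sf_params
                )
        for a in agents:
            speed = float(np.linalg.norm(a.position - prev[a.id])) / params.dt
            a.speed_history.append(speed)
            a.swap_cooldown = max(0, a.swap_cooldown - 1)
        state.step_index = step
        state.clock = step * params.dt
        record(step + 1)
        if scenario.target.contains(walker.position):
            crossed = True
            break

    trajectory = Trajectory(
        frame_interval=params.dt,
        records=pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS),
    )
    summary = summarize_run(trajectory, walker.id, scenario, crossed, seed)
    if return_state:
        return trajectory, summary, state
    return trajectory, summary


def summarize_run(
    trajectory: Trajectory,
    walker_id: int,
    scenario: Scenario,
    crossed: bool,
    seed: int,
) -> RunSummary:
    """Walker statistics measured with the analysis toolkit, so simulation
    and experiment-style input are measured identically."""
    positions = trajectory.positions_of(walker_id)
    stats = analysis.region_stats(
        positions, trajectory.frame_interval, scenario.waiting_area
    )
    return RunSummary(
        crossed=crossed,
        duration_in_area=stats.duration_in_area,
        mean_speed_inside=stats.v_inside,
        mean_speed_outside=stats.v_outside,
        seed=seed,
    )


def run_batch(
    scenario: Scenario,
    n_runs: int,
    base_seed: int,
    jitter_x: float = 0.3,
    psychology: bool = True,
    locomotion: str = "osm",
) -> list[RunSummary]:
    """Repeat the crossing with slightly varying walker start positions.

    Run ``i`` uses seed ``base_seed + i`` and a walker start jittered
    uniformly by +/- ``jitter_x`` metres in x; the waiting crowd keeps
    identical positions across all runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    jitter_rng = np.random.default_rng(base_seed)
    offsets = (
        jitter_rng.uniform(-jitter_x, jitter_x, size=n_runs)
        if jitter_x > 0
        else np.zeros(n_runs)
    )
    summaries: list[RunSummary] = []
    for i in range(n_runs):
        walker = scenario.walking_agent_spec
        x0, y0 = walker.initial_position
        jittered = dataclasses.replace(
            walker, initial_position=(x0 + float(offsets[i]), y0)
        )
        run_scenario = dataclasses.replace(scenario, walking_agent_spec=jittered)
        _, summary = run_simulation(
            run_scenario, base_seed + i, psychology=psychology, locomotion=locomotion
        )
        summaries.append(summary)
    return summaries
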