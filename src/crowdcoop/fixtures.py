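"""Synthetic trajectory fixtures with known kinematics.

These stand in for tracked video trajectories when exercising the analysis
pipeline: every fixture's speeds, displacements and dwell times are known
by construction, so analysis output can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .engine import TRAJECTORY_COLUMNS, Trajectory

__all__ = ["FixtureSpec", "generate_fixture"]

KINDS = ("constant_velocity", "out_and_back", "random_walk", "blocked_then_cross")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a single-agent synthetic trajectory.

    kind
        constant_velocity: straight walk along +y at ``speed``;
        out_and_back: triangular walk +y to ``amplitude`` and straight back;
        random_walk: seeded Gaussian per-frame steps with r.m.s. step
        ``speed / fps``;
        blocked_then_cross: walk, stand still for the middle third, walk on.
    """

    kind: str
    speed: float = 1.34
    fps: float = 25.0
    duration: float = 2.0
    seed: int = 0
    amplitude: float = 0.5
    start: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be > 0")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")


def generate_fixture(spec: FixtureSpec) -> Trajectory:
    """Build the trajectory (agent id 1) with exactly fps * duration frames."""
    n = int(round(spec.fps * spec.duration))
    dt = 1.0 / spec.fps
    t = np.arange(n) * dt
    x0, y0 = spec.start

    if spec.kind == "constant_velocity":
        x = np.full(n, x0)
        y = y0 + spec.speed * t
    elif spec.kind == "out_and_back":
        # triangular profile: the apex frame carries exactly `amplitude`
        # and the final frame returns exactly to the start
        k = max((n - 1) // 2, 1)
        i = np.arange(n)
        y = y0 + spec.amplitude * np.minimum(np.minimum(i, n - 1 - i), k) / k
        x = np.full(n, x0)
    elif spec.kind == "random_walk":
        rng = np.random.default_rng(spec.seed)
        steps = rng.normal(0.0, spec.speed * dt / np.sqrt(2.0), size=(n - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        x, y = x0 + pos[:, 0], y0 + pos[:, 1]
    else:  # blocked_then_cross
        third = n // 3
        y = np.empty(n)
        y[:third] = spec.speed * t[:third]
        y[third : 2 * third] = y[third - 1] if third else 0.0
        resume = t[2 * third :] - t[2 * third] + dt
        base = y[2 * third - 1] if third else 0.0
        y[2 * third :] = base + spec.speed * resume
        y += y0
        x = np.full(n, x0)

    records = pd.DataFrame(
        {
            "timeStep": np.arange(1, n + 1),
            "pedestrianId": 1,
            "x": x,
            "y": y,
            "selfCategory": None,
        }
    )[TRAJECTORY_COLUMNS]
    return Trajectory(frame_interval=dt, records=records)
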