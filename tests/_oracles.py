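"""Independent brute-force oracles used across the test suite.

These deliberately re-derive quantities with naive loops so they stay
independent of the library code paths they check.
"""

import math

import numpy as np


def min_pairwise_distance(points):
    points = np.asarray(points, dtype=float)
    best = math.inf
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            best = min(best, float(np.linalg.norm(points[i] - points[j])))
    return best


def neighbours_within(observer_pos, observer_id, agents, r):
    """(distance, id) of agents within the closed ball, naive filter."""
    out = []
    for a in agents:
        if a.id == observer_id:
            continue
        d = math.hypot(
            a.position[0] - observer_pos[0], a.position[1] - observer_pos[1]
        )
        if d <= r:
            out.append((d, a.id))
    out.sort()
    return out


def displacement_metrics(positions):
    positions = np.asarray(positions, dtype=float)
    end = float(np.linalg.norm(positions[-1] - positions[0]))
    best = 0.0
    for p in positions:
        best = max(best, float(np.linalg.norm(p - positions[0])))
    return end, best


def rect_contains(bounds, point):
    xmin, ymin, xmax, ymax = bounds
    return xmin <= point[0] <= xmax and ymin <= point[1] <= ymax
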