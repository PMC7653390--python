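# Methods

## Model overview

The simulator couples a standard microscopic locomotion layer with a
psychology layer that runs first in every time step. The world is a 4 m ×
7 m corridor (origin bottom-left, walking direction +y) containing a
1.55 m × 1.70 m waiting area whose entrance edge sits at y = 2.65 m,
flanked left and right by impassable tables, with a source region below
and a target region above. Thirteen waiting agents stand on a fixed
staggered lattice inside the area (3-2-3-2-3 agents per row); one walking
agent starts centred at the bottom edge of the source region. With the
walker inside the area the crowd density is 14 / 2.635 m² ≈ 5.3 ped/m² —
dense enough that no collision-free path exists.

Each step, every agent (in a seeded random order):

1. **perceives** the agents within radius *r* (closed ball, sorted by
   distance then id);
2. **updates its self-category** from its own speed history: if all of the
   last *n* recorded speeds are below *v*<sub>thr</sub> it becomes
   COOPERATIVE; if the mean of the last *n* speeds is at or above
   *v*<sub>thr</sub> it reverts (walker → TARGET_ORIENTED, waiter → WAIT);
   otherwise it keeps its category. The rule reads only the percept and
   the agent's own history — no global state;
3. **acts**: waiters (agents without a target) never move. A
   target-oriented walker takes one optimal-steps stride. A cooperative
   walker looks for a perceived cooperative neighbour strictly closer to
   its target; if one exists, the pair exchange positions within the step
   (ties to the smaller id, both partners barred from acting again until
   the next step), otherwise it falls back to locomotion.

Speed histories are filled from realised displacements (‖Δp‖/dt), so the
cognition rule sees exactly the speeds the output trajectory implies —
including the large one-step speed a swap produces, which is what flips a
walker back to target-oriented right after each exchange.

### Locomotion

The optimal-steps chooser evaluates 16 directions × 4 radii plus staying
put on a disc of radius *v*·dt (one stride). One candidate spoke is
aligned with the target azimuth, so unobstructed walking is exactly
straight at full speed. Utility is target distance (Euclidean distance to
the nearest point of the target region; the corridor is convex so this is
the geodesic) minus exponential repulsions in the surface gap to agents
and obstacles. Admissibility is hard: candidates that would overlap a
torso disc (centre distance < 2·r_body − 1e−9), an obstacle, or the domain
boundary are discarded; with no admissible improving candidate the agent
stays and records speed 0.

Two deliberate numerical choices:

* **A move must strictly beat staying put** (by > 1e−12). If staying could
  lose ties, an agent wedged against the crowd could oscillate between
  equal-utility footholds at super-threshold speed and never become
  cooperative.
* **The summed repulsion gradient must stay below the target gradient.**
  With several torsos in contact the agent-repulsion gradients add; if
  their sum exceeded *w_target* a blocked walker would retreat (or stall
  out of swap reach) instead of standing still at contact. The defaults
  (w_target = 1, w_agent = 0.1, range 0.3 m, ≈4 close neighbours) keep the
  worst-case sum near 0.7.

The social-force baseline (driving force towards the target plus
exponential repulsions, explicit Euler, speed capped at the free-flow
value, displacement clamped to preserve non-overlap) exists to demonstrate
the classic failure mode: at ρ ≈ 5.3 the walker is held at an equilibrium
standoff and makes < 0.2 m of progress in 60 s.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| dt | 0.4 | s | one stride duration; 22 in-area steps at ~0.45 s/step match the ~10 s dwell times such crossings take, and 1.34 m/s × 0.4 s ≈ 0.54 m is a natural step length |
| r | 0.5 | m | swap-partner search radius ≈ one stride, so exchanges happen between bodily adjacent agents; a larger r lets the walker leapfrog whole rows in one swap, contrary to the observed row-by-row zig-zag |
| n_history | 3 | steps | a blocked agent turns cooperative after ~1.2 s; free walking (≥ 0.5 m/s) can never trigger it |
| v_threshold | 0.05 | m/s | far below any realisable moving speed (the smallest candidate stride at the slowest walker is ≈ 0.13 m/s), so "cannot move" means exactly that |
| body_radius | 0.195 | m | common torso radius in microscopic models; makes 13 non-overlapping waiters at ρ = 5.3 feasible |
| v_free mean/sd | 1.34 / 0.26 | m/s | empirical free-flow walking speed distribution, truncated to [0.5, 2.2] |
| t_max | 60 | s | generous horizon: a free crossing takes ~5 s, a cooperative one ~15 s |
| jitter_x | ±0.3 | m | per-run variation of the walker start; the crowd lattice is identical across runs |
| w_target, w_agent, w_obstacle | 1.0, 0.1, 0.1 | – | see the gradient argument above |

The waiting-crowd lattice anchors its front row one body diameter plus a
0.15 m standoff behind the entrance edge. This is a measurement-driven
design choice: a walker halted at contact distance from the front row then
stands *inside* the waiting area, so the in-area clock starts when the
interaction starts and the free-flow measurement strip (same width,
1.5 m deep, directly before the entrance) contains only unhindered
walking. A generic centred-grid placement (`place_waiting_crowd`) is also
provided for other scenarios.

## What a run produces

`run_simulation` yields a frame-indexed multi-agent `Trajectory`
(dt-spaced, frame indices from 1, with per-frame self-categories) and a
`RunSummary` whose inside/outside mean speeds and dwell time are computed
by the same analysis code that handles external trajectory tables.
`run_batch` repeats the run with seeds base+i and jittered starts.
Everything is bit-reproducible per seed.

Typical behaviour at the defaults: the walker approaches at its free-flow
speed, halts at the front row, turns cooperative after three sub-threshold
steps, and crosses with five row-by-row swaps separated by three-step
waiting intervals (the post-swap speed spike resets the cognition rule),
then walks out freely — about 8 s inside the area, with inside mean speed
~0.3 m/s against ~1.34 m/s outside.

## Analysis conventions

* Instantaneous speed is a backward difference; the speed at frame t is
  ‖p(t) − p(t−1)‖/ΔT and belongs to frame t. Frame masks are applied
  accordingly (the first frame carries no speed).
* "Inside" uses the closed waiting-area rectangle: a frame exactly on the
  boundary is inside. The outside strip excludes frames that are inside,
  so no frame is double counted.
* Dwell time is inside-frame count × ΔT, hence quantised to one frame.
* The paired one-sided t-test uses the sample standard deviation (N − 1)
  and the lower 0.05 quantile of Student's t with N − 1 d.f.
* The KS survey fits each candidate family by maximum likelihood and uses
  the asymptotic one-sample KS p-value *without* fitted-parameter
  correction; retention is strict (p > cutoff). With estimated parameters
  these p-values are optimistic and fluctuate between sample draws — the
  survey ranks candidate families, it is not a calibrated test.

## The synthetic fixtures

`fixtures.generate_fixture` builds single-agent trajectories with known
kinematics (constant velocity, triangular out-and-back, seeded random
walk, walk–stand–walk). They emulate the *format* and the controlled
kinematic content of tracked-video trajectories, not their measurement
noise, head sway, or inter-person correlations. Tests passing on fixtures
therefore validate the measurement pipeline's arithmetic and conventions,
not the simulator's fidelity to any particular empirical dataset.

## Problem sizes

The shipped batch size is 100 runs (the scale of the study being
re-enacted); a batch takes a few seconds on one core, so all batch-level
checks run at full size.

## Known limitations

* Waiters in WAIT are perfectly immobile, so their displacement metrics
  are identically zero; the displacement statistics are exercised on
  synthetic fixtures instead.
* The inside mean speed (~0.3 m/s) sits between a fully blocked and a
  continuously moving walker; its exact value depends on step-timing
  details (dt, candidate radii, cooldown) more than any other output.
* Only pairwise swaps are modelled — no chains, no verbal negotiation, no
  external stimuli; the crowd gives way only by exchanging places with
  the walker.
* The fixed-step sequential update (random agent order per step) is a
  declared scheme, not the only possible one; conservation and
  non-overlap invariants hold for any order, but exact trajectories
  depend on the seed.
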