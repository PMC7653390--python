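# Scenario configuration files

`save_scenario` / `load_scenario` (and the CLI `--scenario` option) use a
YAML or JSON document (chosen by file extension) with the following keys.
All lengths are metres, times are seconds, speeds m/s.

```yaml
domain_bounds:            # rectangular simulation domain
  kind: rectangle         # "rectangle" (axis-aligned) or "polygon"
  vertices: [[0.0, 0.0], [4.0, 0.0], [4.0, 7.0], [0.0, 7.0]]
waiting_area:             # the delimited area the crowd occupies
  kind: rectangle
  vertices: [[1.225, 2.65], [2.775, 2.65], [2.775, 4.35], [1.225, 4.35]]
source:                   # where the walker starts (below the area)
  kind: rectangle
  vertices: [[1.225, 0.1], [2.775, 0.1], [2.775, 0.9], [1.225, 0.9]]
target:                   # what the walker steers for (above the area)
  kind: rectangle
  vertices: [[1.225, 6.1], [2.775, 6.1], [2.775, 6.9], [1.225, 6.9]]
obstacles:                # impassable regions (the flanking tables)
  - {kind: rectangle, vertices: [[0.0, 2.65], [1.225, 2.65], [1.225, 4.35], [0.0, 4.35]]}
  - {kind: rectangle, vertices: [[2.775, 2.65], [4.0, 2.65], [4.0, 4.35], [2.775, 4.35]]}
walking_agent:
  id: 1
  initial_position: [2.0, 0.1]
  role: walker
  free_flow_speed: null   # null -> drawn from the truncated normal per run
waiting_agents:           # fixed positions, identical across batch runs
  - {id: 2, initial_position: [1.44, 3.19], role: waiter, free_flow_speed: 1.34}
  # ... one entry per waiting agent
params:
  dt: 0.4                 # step interval (s)
  r: 0.5                  # perception / swap search radius (m)
  n_history: 3            # speed-history length (steps)
  v_threshold: 0.05       # cooperative-switch speed threshold (m/s)
  body_radius: 0.195      # torso radius (m)
  v_free_mean: 1.34       # free-flow speed distribution (m/s)
  v_free_sd: 0.26
  v_free_min: 0.5
  v_free_max: 2.2
  t_max: 60.0             # simulation horizon (s)
  seed: 0
```

Constraints enforced on load: regions non-degenerate and inside the
domain; source below and target above the waiting area along y; unique
agent ids; no agent's torso disc overlapping an obstacle; all `params`
positive with `n_history >= 1` and `v_threshold < v_free_mean`.

Trajectory files are tab-separated tables with header
`timeStep pedestrianId x y selfCategory` (the last column optional on
read), frame indices starting at 1; see `crowdcoop.trajio`.
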