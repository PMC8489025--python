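# hexnav

Graph-based analysis and generative modelling of rodent navigation in the
**HexMaze** — a large modular maze of six hexagonal modules packed around a
central hexagonal circuit, giving 24 intersection nodes (twelve two-way and
twelve three-way choice points) joined by 30 gangways.  Mice learn to run
from varying start nodes to a rewarded goal node; because the maze
discretizes behavior into node sequences, every trial is fully described by
the list of choice points visited.

`hexnav` is for researchers analysing such node-sequence trajectories (real
or simulated): it quantifies goal-directed performance trial by trial,
parametrizes within-trial search structure, and fits a minimal two-parameter
generative model of navigation so that learning can be expressed as the
evolution of interpretable parameters.

## What it computes

**Trial statistics.** For a trial from start *s* to goal *g*:

- **RTL** (relative trial length) = edges traversed until first goal
  arrival / *d(s, g)*; RTL = 1 is a perfect trial, and `log10(RTL)` = 0.
- **DFOP** (distance from optimal path): at each visited node *v*,
  `min over u in O(s, g) of d(v, u)` where *O(s, g)* is the set of nodes on
  *any* shortest *s*→*g* path (enumerated exactly by bidirectional BFS; a
  noisy-edge-weight variant reproduces the same sets stochastically).
  Group-averaged DFOP profiles form a bump, parametrized as a normalized
  difference of Gaussians

  ```
  g(x) = A · (exp(-x²/2L1²) − exp(-x²/2L2²)) / Z,   L1 > L2 > 0,
  ```

  with Z chosen so max g = A: peak stray **A** (edges), ascent scale **L2**
  and descent scale **L1** (steps), fitted by bounded multi-start least
  squares.
- Outer-ring occupancy, node crossings, the trial binning used throughout
  (trial 1, 2–11, 12–21, 22–31 per session), goal-shuffle surrogates
  (surrogate RTL = 10 when the trajectory never visits the shuffled goal),
  and 50-fold bootstrap summaries.

**Generative navigator.** A virtual mouse moves node to node, never
reversing, with two parameters:

- **η** — per-step probability of committing to a "diagonal run": a
  shortest path toward a random outer-ring node ≥ 3 edges away;
- **F** (*foresight*) — at every node arrival it draws
  x ~ Exponential(mean F) and, if its distance to the goal is < x, runs
  straight to the goal.  F = 0 is a memoryless searcher; F ≫ maze diameter
  reproduces perfect trials.

**Strategy fitting.** `fit_strategy` scans an (η, F) grid (defaults
η ∈ 0…0.2 step 0.02, F ∈ 0…4 step 0.1), simulating runs for each observed
trial's start–goal pair, and minimizes the two-sample Kolmogorov–Smirnov
distance between observed and simulated RTL distributions (common random
numbers across grid points; near-ties resolve to the smallest η).  Max-DFOP
and outer-ring occupancy distributions are held out and compared only at
the best pair.  `foresight_trajectory` repeats this per trial bin with a
bootstrap spread, turning learning curves into trajectories of (η, F).

**Synthetic data.** `generate_protocol` reproduces the experimental
start-location rules (starts ≥ 2 choice points from goal and previous
start, no consecutive repeats, ≥ 60% unique-geodesic trials, session-first
constraints, goals counterbalanced 1-in-4 on the inner ring; barrier
updates remove 1–3 gangways while keeping the maze connected and rerouting
geodesics from ≥ 50% of starts).  `generate_dataset` drives the navigator
with a known per-bin (η, F) schedule so every pipeline stage can be tested
by parameter recovery.

## A worked example

```bash
python examples/random_walk_baseline.py
```

```
start-goal pairs: 372, simulated runs: 18600
mean log10 RTL = 0.640   (circa 0.6: ~4x the shortest path)
geometric-mean RTL = 4.37
median RTL = 4.60
```

A memoryless navigator (η = 0, F = 0) takes on average about four times the
shortest path — mean log₁₀ RTL near 0.6.  That is the floor against which
learning is measured; trained behavior sits around 0.2–0.3 (1.5–2× the
shortest path), which the navigator reaches at foresight values below 2:

```bash
python examples/strategy_recovery.py   # recovers (eta, F) from simulated data
python examples/trial_metrics_and_dog.py
python examples/shuffle_control.py     # the goal-shuffle specificity control
python examples/maze_tour.py
```

The same pipeline is scriptable from the shell:

```bash
hexnav simulate --animals 4 --foresight 1.0 --seed 7 --out trials.csv
hexnav metrics  --trajectories trials.csv --out metrics.csv
hexnav fit      --trajectories trials.csv --condition build_up --session 1 \
                --bin t2_11 --reps 50 --seed 7 --out fit.json
hexnav report   --trajectories trials.csv --seed 7 --out report.csv
```

## Layout

```
src/hexnav/      maze.py        maze graph, geodesic sets, serialization
                 trajectory.py  trial container, bins, validation
                 metrics.py     RTL, DFOP, shuffles, bootstraps
                 dog.py         difference-of-Gaussians fit
                 simulate.py    the (eta, F) navigator
                 strategy.py    KS grid fit and per-bin trajectories
                 synth.py       protocols, schedules, ground-truth datasets
                 io.py          long-form trajectory CSV
                 cli.py         the `hexnav` command
examples/        one short narrative script per capability
docs/methods.md  model, assumptions, numerical choices, limitations
```
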