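"""Generative model of HexMaze navigation.

A virtual mouse moves node-to-node with three ingredients:

* **random search** — at each step it picks uniformly among the current
  node's neighbors, excluding the node it just came from (no immediate
  reversals); at the start node all neighbors are eligible;
* **diagonal runs** — with per-step probability ``eta`` (while searching) it
  commits to a shortest path toward a uniformly chosen outer-ring node at
  least 3 edges away, resuming random search on arrival;
* **foresight** — on every node arrival it draws x ~ Exponential(mean F);
  if the shortest-path distance to the goal is smaller than x, it runs
  straight to the goal along a (randomly chosen) geodesic and the trial
  ends.  F = 0 never triggers: such an agent finds the goal only by
  stepping on it.

Trials end at first goal arrival, or are censored (``completed=False``)
after ``max_steps`` steps.  The foresight check also runs during diagonal
runs, and a new run cannot start while one is in progress.  Committed runs
(diagonal or foresight) are chosen so their first step does not reverse the
previous move; in the rare case every geodesic would, the run follows a
shortest path computed with the just-used gangway excluded.

Numerically, the walk consumes exactly three uniforms per step — foresight
check (compared against the exponential survival function exp(-d/F),
equivalent to drawing the exponential directly), diagonal-run check, and
move choice — plus extra draws only at committed-run events.  The fixed
layout means walks driven by the same seed stay step-for-step identical
across parameter values until a decision actually differs, which lets grid
searches use common random numbers as a variance-reduction device.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._util import UniformStream, as_generator
from .errors import DegenerateTrialError, ParameterError
from .maze import MazeGraph
from .trajectory import Trajectory

#: minimum distance (edges) to an eligible diagonal-run target
DIAGONAL_MIN_DISTANCE = 3


@dataclass(frozen=True)
class SimParams:
    """Navigator parameters.

    eta
        Per-step probability, while in random search, of initiating a
        diagonal run to the outer ring.
    foresight
        Mean F (edges) of the exponential goal-detection distribution.
        Larger F detects the goal from farther away; F = 0 is a memoryless
        searcher.
    max_steps
        Censoring cap on trajectory length.
    """

    eta: float = 0.0
    foresight: float = 0.0
    max_steps: int = 5000

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ParameterError(f"eta must be in [0, 1], got {self.eta}")
        if self.foresight < 0:
            raise ParameterError(f"foresight must be >= 0, got {self.foresight}")
        if self.max_steps < 1:
            raise ParameterError("max_steps must be positive")


def foresight_triggered(d: int, foresight: float, rng=None) -> bool:
    """Draw x ~ Exponential(mean F) and report whether ``d < x``.

    The trigger probability at distance d is the exponential survival
    function exp(-d/F); F = 0 never triggers for d > 0.
    """
    if d < 0:
        raise ParameterError(f"distance must be >= 0, got {d}")
    if foresight < 0:
        raise ParameterError(f"foresight must be >= 0, got {foresight}")
    if foresight == 0.0:
        return False
    rng = as_generator(rng)
    return d < rng.exponential(foresight)


def _diagonal_targets(maze: MazeGraph) -> dict:
    """Outer-ring nodes at distance >= 3, per node (precomputed, cached)."""
    cache = getattr(maze, "_diag_targets", None)
    if cache is None:
        outer = maze.outer_nodes
        cache = {v: tuple(t for t in outer if maze.distance(v, t) >= DIAGONAL_MIN_DISTANCE)
                 for v in maze.nodes}
        maze._diag_targets = cache
    return cache


def _move_candidates(maze: MazeGraph) -> dict:
    """No-reversal move options keyed by (current, previous); previous=None
    at the start node (precomputed, cached)."""
    cache = getattr(maze, "_move_cand", None)
    if cache is None:
        cache = {}
        for v in maze.nodes:
            nbrs = maze._neighbors[v]
            cache[(v, None)] = nbrs
            for p in nbrs:
                cache[(v, p)] = tuple(n for n in nbrs if n != p) or nbrs
        maze._move_cand = cache
    return cache


def _survival_table(maze: MazeGraph, foresight: float) -> list:
    """exp(-d/F) for d = 0..diameter (cached per maze and F)."""
    cache = getattr(maze, "_surv_cache", None)
    if cache is None:
        cache = maze._surv_cache = {}
    tab = cache.get(foresight)
    if tab is None:
        tab = [math.exp(-d / foresight) for d in range(maze.diameter + 1)]
        cache[foresight] = tab
    return tab


def _committed_run(maze: MazeGraph, cur: int, target: int, prev, u: float) -> tuple:
    """Remaining nodes of a run from ``cur`` to ``target`` avoiding reversal.

    Picks uniformly (via the uniform draw ``u``) among geodesics whose first
    step is not ``prev``; if every geodesic reverses, falls back to a
    shortest path with the (cur, prev) gangway excluded.
    """
    geos = maze.geodesics(cur, target)
    ok = [g for g in geos if len(g) < 2 or g[1] != prev]
    if ok:
        return ok[int(u * len(ok))][1:]
    h = nx.restricted_view(maze.graph, [], [(cur, prev)])
    alts = tuple(tuple(p) for p in nx.all_shortest_paths(h, cur, target))
    return alts[int(u * len(alts))][1:]


def _walk(maze: MazeGraph, start: int, goal: int, eta: float, F: float,
          max_steps: int, u) -> tuple:
    """Core navigation loop; returns (node tuple, completed flag).

    ``u`` is any object with a ``next() -> float in [0, 1)`` method.
    """
    dist_goal = maze._dist[goal]
    surv = _survival_table(maze, F) if F > 0 else None
    targets = _diagonal_targets(maze) if eta > 0 else None
    moves = _move_candidates(maze)
    unext = u.next

    path = [start]
    cur, prev = start, None
    run = ()  # remaining nodes of a committed diagonal run
    ri = 0
    while len(path) - 1 < max_steps:
        if cur == goal:
            return tuple(path), True
        # fixed per-step layout: foresight draw, run-initiation draw, move draw
        u_fore = unext()
        u_eta = unext()
        u_move = unext()
        if surv is not None and u_fore < surv[dist_goal[cur]]:
            tail = _committed_run(maze, cur, goal, prev, unext())
            room = max_steps - (len(path) - 1)
            path.extend(tail[:room])
            return tuple(path), len(tail) <= room
        if ri < len(run):
            nxt = run[ri]
            ri += 1
        elif targets is not None and u_eta < eta and targets[cur]:
            cand = targets[cur]
            tgt = cand[int(unext() * len(cand))]
            run = _committed_run(maze, cur, tgt, prev, unext())
            nxt, ri = run[0], 1
        else:
            run, ri = (), 0
            nn = moves[(cur, prev)]
            nxt = nn[int(u_move * len(nn))]
        path.append(nxt)
        prev, cur = cur, nxt
    return tuple(path), path[-1] == goal


def simulate_trial(maze: MazeGraph, start: int, goal: int, params: SimParams,
                   rng=None, **meta) -> Trajectory:
    """Simulate one trial; extra keyword arguments become trial metadata."""
    if start == goal:
        raise DegenerateTrialError(f"start == goal == {start}")
    maze._check_node(start)
    maze._check_node(goal)
    rng = as_generator(rng)
    nodes, completed = _walk(maze, start, goal, params.eta, params.foresight,
                             params.max_steps, UniformStream(rng, block=96))
    return Trajectory(nodes=nodes, goal=goal, completed=completed, **meta)


def simulate_dataset(maze: MazeGraph, trial_specs, params: SimParams,
                     n_reps: int = 50, rng=None, **meta) -> list:
    """``n_reps`` independent trajectories per (start, goal) spec.

    Mirrors the augmentation scheme of the model analysis: 50 simulated runs
    per experimental trial.  Fixed rng state gives bitwise-identical output.
    """
    if not trial_specs:
        raise ParameterError("trial_specs must be nonempty")
    rng = as_generator(rng)
    out = []
    for start, goal in trial_specs:
        for _ in range(n_reps):
            out.append(simulate_trial(maze, start, goal, params, rng=rng, **meta))
    return out
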