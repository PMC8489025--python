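"""Trial-level and sub-trial behavioral statistics.

Two quantities carry most of the analysis:

* **RTL** (relative trial length): edges traversed until first goal arrival,
  divided by the shortest-path length from start to goal.  RTL = 1 means the
  animal took a geodesic.  Lengths are counted in *edges*, so a perfect trial
  scores exactly 1 and ``log10(RTL)`` exactly 0.
* **DFOP** (distance from optimal path): at each visited node, the graph
  distance to the nearest node lying on *any* shortest start-goal path.
  Averaged over a trial group, step by step, the DFOP profile shows the
  characteristic rise-then-fall "stray" bump of non-optimal search.

Per-"time" statistics are per visited node (graph steps); no wall-clock
timestamps enter the analysis.  Ring occupancy is therefore node-weighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._util import as_generator
from .errors import DegenerateTrialError, ParameterError
from .maze import MazeGraph
from .trajectory import Trajectory

#: RTL assigned to a shuffled-goal surrogate trial that never reaches its
#: surrogate goal (the conventional penalty value of the shuffle analysis).
SHUFFLE_DEFAULT_RTL = 10.0


@dataclass(frozen=True)
class TrialMetrics:
    """Summary statistics of one (possibly surrogate) trial."""

    rtl: float
    log_rtl: float
    max_dfop: int
    outer_fraction: float
    path_steps: int


@dataclass(frozen=True)
class DFOPProfile:
    """Per-step mean/SD/count of DFOP across a trial group."""

    step: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    horizon: int


def _path_to_goal(t: Trajectory, goal=None) -> tuple:
    """Visited nodes up to and including the first arrival at the goal."""
    goal = t.goal if goal is None else goal
    try:
        idx = t.nodes.index(goal)
    except ValueError:
        return t.nodes
    return t.nodes[: idx + 1]


def _outer_fraction(nodes, maze: MazeGraph) -> float:
    return sum(1 for v in nodes if maze.ring[v] == "outer") / len(nodes)


def dfop_series(t: Trajectory, maze: MazeGraph, goal=None) -> list:
    """DFOP at every visited node, relative to the start→goal geodesic set.

    For a completed trial both the first and last values are 0, since the
    start and the goal lie on the optimal-path set by definition.
    """
    goal = t.goal if goal is None else goal
    opt = maze.optimal_path_set(t.start, goal)
    nodes = _path_to_goal(t, goal)
    return [min(maze.distance(v, w) for w in opt.nodes) for v in nodes]


def relative_trial_length(t: Trajectory, maze: MazeGraph) -> TrialMetrics:
    """RTL and companion statistics of one completed trial.

    Raises :class:`DegenerateTrialError` if the trial is incomplete or
    start == goal (the ratio is undefined at distance 0).
    """
    if t.start == t.goal:
        raise DegenerateTrialError(f"start == goal == {t.start}: RTL undefined")
    if not t.completed or t.goal not in t.nodes:
        raise DegenerateTrialError(
            "trial never reached its goal; RTL is only defined for completed trials")
    nodes = _path_to_goal(t)
    steps = len(nodes) - 1
    dist = maze.distance(t.start, t.goal)
    rtl = steps / dist
    series = dfop_series(t, maze)
    return TrialMetrics(
        rtl=rtl,
        log_rtl=math.log10(rtl),
        max_dfop=int(max(series)),
        outer_fraction=_outer_fraction(nodes, maze),
        path_steps=steps,
    )


def dfop_profile(trials: Sequence[Trajectory], maze: MazeGraph,
                 horizon: Optional[int] = None, pad: bool = True) -> DFOPProfile:
    """Per-step mean/SD/count of DFOP across a group of trials.

    ``horizon`` defaults to the 95th percentile of the group's trial lengths
    (in steps).  With ``pad=True`` (default) completed trials contribute 0
    after goal arrival up to the horizon — the goal lies on the optimal
    path, so a distance-0 continuation is the natural extension and lets the
    group mean converge to zero instead of being dominated by survivors.
    """
    if not trials:
        raise ParameterError("dfop_profile requires a nonempty trial group")
    series = [dfop_series(t, maze) for t in trials]
    if horizon is None:
        horizon = int(np.percentile([len(s) - 1 for s in series], 95))
    h = int(horizon)
    steps = np.arange(h + 1)
    cols = []
    for s in series:
        col = np.full(h + 1, np.nan)
        upto = min(len(s), h + 1)
        col[:upto] = s[:upto]
        if pad and len(s) <= h:
            col[len(s):] = 0.0
        cols.append(col)
    mat = np.vstack(cols)
    n = np.sum(~np.isnan(mat), axis=0)
    denom = np.maximum(n, 1)
    mean = np.where(n > 0, np.nansum(mat, axis=0) / denom, np.nan)
    sq = np.nansum((mat - np.where(np.isnan(mean), 0.0, mean)) ** 2, axis=0)
    sd = np.where(n > 0, np.sqrt(sq / denom), np.nan)
    return DFOPProfile(step=steps, mean=mean, sd=sd, n=n, horizon=h)


def optimal_trial_probability(trials: Sequence[Trajectory], maze: MazeGraph,
                              threshold: float = 1.5, n_boot: int = 50,
                              rng=None) -> tuple:
    """Fraction of trials with RTL below ``threshold``, with bootstrap SD.

    RTL < 1.5 is the conventional definition of an "optimal trial".
    """
    rtls = np.array([relative_trial_length(t, maze).rtl for t in trials])
    frac = float(np.mean(rtls < threshold))
    if len(rtls) < 2:
        return frac, 0.0
    rng = as_generator(rng)
    boots = [np.mean(rng.choice(rtls, size=len(rtls), replace=True) < threshold)
             for _ in range(n_boot)]
    return frac, float(np.std(boots))


def node_crossings(t: Trajectory, nodes) -> dict:
    """How many times each queried node appears in the trajectory."""
    seq = t.nodes
    return {v: seq.count(v) for v in nodes}


def bootstrap_summary(values, n_boot: int = 50, rng=None) -> tuple:
    """Bootstrap mean and SD of the sample mean (n resamples with replacement)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("bootstrap_summary requires a nonempty sample")
    rng = as_generator(rng)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    return float(means.mean()), float(means.std())


def _surrogate_metrics(t: Trajectory, goal: int, maze: MazeGraph) -> TrialMetrics:
    """Metrics of one trial re-scored against a surrogate goal."""
    if goal in t.nodes:
        nodes = _path_to_goal(t, goal)
        steps = len(nodes) - 1
        rtl = steps / maze.distance(t.start, goal)
    else:
        nodes = t.nodes
        steps = len(nodes) - 1
        rtl = SHUFFLE_DEFAULT_RTL
    series = dfop_series(t, maze, goal=goal)
    return TrialMetrics(
        rtl=rtl,
        log_rtl=math.log10(rtl),
        max_dfop=int(max(series)),
        outer_fraction=_outer_fraction(nodes, maze),
        path_steps=steps,
    )


def gl_shuffle(trials: Sequence[Trajectory], maze: MazeGraph, rng=None,
               max_tries: int = 1000) -> list:
    """Surrogate metrics after shuffling goal labels across a trial block.

    Goals are permuted (without replacement) across the block's trials; each
    trial is re-scored against its surrogate goal using the sub-trajectory
    up to the goal's first occurrence.  Trials that never visit their
    surrogate goal receive the conventional RTL of 10.  An assignment that
    would give a trial its own start node as surrogate goal (undefined RTL)
    is repaired by swapping with a compatible position; blocks where no
    conflict-free permutation can be arranged raise an error.
    """
    if len(trials) < 2:
        raise ParameterError("gl_shuffle requires at least 2 trials in the block")
    rng = as_generator(rng)
    goals = [t.goal for t in trials]
    n = len(goals)
    perm = list(rng.permutation(n))

    def ok(k, j):
        return goals[j] != trials[k].start

    for _ in range(max_tries):
        conflicts = [k for k in range(n) if not ok(k, perm[k])]
        if not conflicts:
            break
        for k in conflicts:
            order = rng.permutation(n)
            for j in order:
                j = int(j)
                if j != k and ok(k, perm[j]) and ok(j, perm[k]):
                    perm[k], perm[j] = perm[j], perm[k]
                    break
    else:
        raise ParameterError(
            "could not arrange a goal permutation avoiding start == surrogate goal")
    return [_surrogate_metrics(t, goals[j], maze) for j, t in zip(perm, trials)]
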