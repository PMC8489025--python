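"""Trajectories and trial grouping.

A trajectory is the ordered sequence of maze nodes an animal (or the
simulator) visited during one trial, together with its trial metadata.
Trials are grouped, within each session, into the four standard bins used
throughout the analysis: the first trial alone, then trials 2-11, 12-21 and
22-31; trials beyond 31 are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import TrajectoryFormatError
from .maze import MazeGraph

CONDITIONS = ("build_up", "location_update", "barrier_update")
BINS = ("first", "t2_11", "t12_21", "t22_31")


def trial_bin(trial_index: int) -> Optional[str]:
    """Map a 1-based trial index to its bin, or None if beyond trial 31."""
    if trial_index < 1:
        raise ValueError(f"trial_index must be >= 1, got {trial_index}")
    if trial_index == 1:
        return "first"
    if trial_index <= 11:
        return "t2_11"
    if trial_index <= 21:
        return "t12_21"
    if trial_index <= 31:
        return "t22_31"
    return None


@dataclass(frozen=True)
class Trajectory:
    """One trial: visited nodes plus metadata.

    ``completed`` means the trial ended by reaching the goal: the last node
    equals the goal and the goal appears nowhere earlier.  Censored
    simulator runs and surrogate trials carry ``completed=False``.
    """

    nodes: tuple
    goal: int
    animal_id: str = "sim"
    condition: str = "build_up"
    session: int = 1
    trial_index: int = 1
    completed: bool = True

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if not self.nodes:
            raise ValueError("trajectory must contain at least one node")

    @property
    def start(self) -> int:
        return self.nodes[0]

    @property
    def steps(self) -> int:
        """Number of edges traversed (length in edges, not nodes)."""
        return len(self.nodes) - 1

    @property
    def bin(self) -> Optional[str]:
        return trial_bin(self.trial_index)

    def with_goal(self, goal: int) -> "Trajectory":
        """Relabel the goal (used by the goal-shuffle surrogate analysis)."""
        completed = goal in self.nodes
        return replace(self, goal=goal, completed=completed)


def validate_trajectory(t: Trajectory, maze: MazeGraph, strict: bool = False,
                        context: str = "") -> list:
    """Check a trajectory against the maze; return a list of problem strings.

    Adjacency violations and unknown nodes are always errors (raised when
    ``strict``); immediate reversals only warn, since real tracking data may
    legitimately contain them while simulator output may not.
    """
    problems = []
    known = set(maze.nodes)
    for i, v in enumerate(t.nodes):
        if v not in known:
            problems.append(f"{context}step {i}: unknown node {v}")
    for i in range(len(t.nodes) - 1):
        a, b = t.nodes[i], t.nodes[i + 1]
        if a in known and b in known and not maze.has_edge(a, b):
            problems.append(f"{context}step {i}->{i + 1}: nodes {a},{b} are not adjacent")
    if t.completed:
        if t.nodes[-1] != t.goal:
            problems.append(f"{context}marked completed but last node {t.nodes[-1]} != goal {t.goal}")
        elif t.goal in t.nodes[:-1]:
            problems.append(f"{context}goal {t.goal} visited before the final step")
    if strict and problems:
        raise TrajectoryFormatError("; ".join(problems))
    for i in range(len(t.nodes) - 2):
        if t.nodes[i + 2] == t.nodes[i]:
            warnings.warn(f"{context}immediate reversal at step {i + 1} "
                          f"({t.nodes[i]}->{t.nodes[i + 1]}->{t.nodes[i + 2]})",
                          stacklevel=2)
            break
    return problems


def group_trials(trials: Sequence[Trajectory]):
    """Group trajectories by (condition, session, bin); trials >31 are dropped.

    Returns a dict mapping ``(condition, session, bin)`` to a list of
    trajectories, with bins ordered as in :data:`BINS` and insertion order
    following (condition, session).
    """
    groups = {}
    for t in trials:
        b = t.bin
        if b is None:
            continue
        groups.setdefault((t.condition, t.session, b), []).append(t)
    def order(key):
        cond, sess, b = key
        ci = CONDITIONS.index(cond) if cond in CONDITIONS else len(CONDITIONS)
        return (ci, sess, BINS.index(b))
    return {k: groups[k] for k in sorted(groups, key=order)}
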