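"""Trajectory dataset I/O.

The on-disk format is a long-form CSV, one row per visited node, with a
mandatory header::

    animal_id,condition,session,trial,step,node,goal

``step`` is 0-based within a trial; ``goal`` repeats the trial's goal node
on every row (files without a goal column are accepted, taking each trial's
last node as its goal).  The loader validates node identities and step
adjacency against a maze and reports violations with file row numbers.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import TrajectoryFormatError
from .maze import MazeGraph
from .trajectory import Trajectory

_REQUIRED = ("animal_id", "condition", "session", "trial", "step", "node")


def write_trajectories(trials: Sequence[Trajectory], path) -> None:
    """Write a dataset in the long-form CSV dialect."""
    rows = []
    for t in trials:
        for i, v in enumerate(t.nodes):
            rows.append((t.animal_id, t.condition, t.session, t.trial_index, i, v, t.goal))
    frame = pd.DataFrame(rows, columns=list(_REQUIRED) + ["goal"])
    frame.to_csv(path, index=False)


def read_trajectories(path, maze: Optional[MazeGraph] = None) -> list:
    """Read a dataset, validating structure (and adjacency, if a maze is given).

    Raises :class:`TrajectoryFormatError` naming the offending file rows;
    immediate reversals only warn, since real tracking data may contain them.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError(f"{path}: file is empty (header mandatory)") from None
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing required columns {missing}")
    if frame.empty:
        warnings.warn(f"{path}: no trajectory rows (empty dataset)", stacklevel=2)
        return []
    for col in ("session", "trial", "step", "node"):
        try:
            frame[col] = frame[col].astype(int)
        except (ValueError, TypeError):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            rows = [int(i) + 2 for i in bad[:5]]
            raise TrajectoryFormatError(
                f"{path}: non-integer values in column {col!r} at rows {rows}") from None
    has_goal = "goal" in frame.columns

    trials = []
    problems = []
    known = set(maze.nodes) if maze is not None else None
    for (animal, cond, sess, trial), sub in frame.groupby(
            ["animal_id", "condition", "session", "trial"], sort=False):
        sub = sub.sort_values("step")
        rows = [int(i) + 2 for i in sub.index]  # +2: header + 1-based
        steps = sub["step"].tolist()
        if steps != list(range(len(steps))):
            problems.append(f"trial {(animal, cond, sess, trial)}: steps not contiguous "
                            f"from 0 (rows {rows[0]}..{rows[-1]})")
            continue
        nodes = sub["node"].tolist()
        if known is not None:
            for v, r in zip(nodes, rows):
                if v not in known:
                    problems.append(f"row {r}: unknown node {v}")
            for i in range(len(nodes) - 1):
                a, b = nodes[i], nodes[i + 1]
                if a in known and b in known and not maze.has_edge(a, b):
                    problems.append(f"row {rows[i + 1]}: step {a}->{b} is not a maze edge")
            for i in range(len(nodes) - 2):
                if nodes[i + 2] == nodes[i]:
                    warnings.warn(f"{path} row {rows[i + 2]}: immediate reversal "
                                  f"{nodes[i]}->{nodes[i + 1]}->{nodes[i]}", stacklevel=2)
                    break
        goal = int(sub["goal"].iloc[0]) if has_goal else int(nodes[-1])
        completed = nodes[-1] == goal and goal not in nodes[:-1]
        trials.append(Trajectory(
            nodes=tuple(nodes), goal=goal, animal_id=str(animal),
            condition=str(cond), session=int(sess), trial_index=int(trial),
            completed=completed))
    if problems:
        raise TrajectoryFormatError(f"{path}: " + "; ".join(problems[:20]))
    return trials
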