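"""Experiment-shaped synthetic protocols and ground-truth datasets.

The generator reproduces the shape of the behavioral protocol — three
conditions (initial map learning, goal relocation, barrier insertion), three
sessions each, up to 31 analyzed trials per session — and the start-location
rules used when the experiment was run:

* starts sit at least 2 choice points from the goal and from the previous
  start, and never repeat in consecutive trials;
* at least 60% of a session's trials admit a unique shortest path;
* a session's first start differs from the previous session's first and
  last starts;
* goals are counterbalanced, one in four on the inner ring.

Trajectories are produced by the generative navigator at known (eta, F) per
trial bin, so recovery of the parameters by the strategy fit can be scored
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._util import as_generator
from .errors import GenerationError, ParameterError
from .maze import MazeGraph, build_hexmaze
from .simulate import SimParams, simulate_trial
from .trajectory import BINS, CONDITIONS, Trajectory, trial_bin

#: attempts allowed when rejection-sampling one session's start sequence
MAX_SESSION_ATTEMPTS = 10_000
#: minimum fraction of trials with a unique shortest path to the goal
UNIQUE_GEODESIC_MIN = 0.6
#: minimum start-to-goal and start-to-start graph distance (edges)
MIN_SEPARATION = 2


@dataclass(frozen=True)
class SessionSpec:
    """One session: its goal, ordered start nodes and barrier set."""

    goal: int
    starts: tuple
    barrier_edges: tuple = ()


@dataclass(frozen=True)
class ProtocolSpec:
    """A full per-animal protocol: one condition, several sessions."""

    condition: str
    sessions: tuple
    trials_per_session: int = 31


@dataclass(frozen=True)
class GroundTruthSchedule:
    """Known (eta, F) per (condition, session, bin) for recovery scoring."""

    table: dict

    def __post_init__(self):
        for key, (eta, f) in self.table.items():
            if not 0.0 <= eta <= 1.0 or f < 0:
                raise ParameterError(f"schedule entry {key} out of bounds: {(eta, f)}")

    def params(self, condition: str, session: int, bin_name: str) -> tuple:
        try:
            return self.table[(condition, session, bin_name)]
        except KeyError:
            raise GenerationError(
                f"schedule has no entry for {(condition, session, bin_name)}") from None

    @classmethod
    def from_bins(cls, per_bin: dict, conditions=CONDITIONS,
                  sessions=(1, 2, 3)) -> "GroundTruthSchedule":
        """Same per-bin (eta, F) for every condition and session."""
        table = {(c, s, b): tuple(per_bin[b])
                 for c in conditions for s in sessions for b in per_bin}
        return cls(table=table)

    @classmethod
    def constant(cls, eta: float, foresight: float, conditions=CONDITIONS,
                 sessions=(1, 2, 3)) -> "GroundTruthSchedule":
        per_bin = {b: (eta, foresight) for b in BINS}
        return cls.from_bins(per_bin, conditions=conditions, sessions=sessions)

    @classmethod
    def build_up_like(cls, condition: str = "build_up") -> "GroundTruthSchedule":
        """Canonical initial-learning scenario: foresight rises within each
        session and across sessions, with a partial rollback on each
        session's first trial (the seesaw of real learning curves), starting
        at 0 (naive animal) and saturating at 2 (the upper end of fitted
        values); eta stays 0 throughout.
        """
        f = {
            1: {"first": 0.0, "t2_11": 0.5, "t12_21": 1.0, "t22_31": 1.25},
            2: {"first": 0.75, "t2_11": 1.25, "t12_21": 1.5, "t22_31": 1.75},
            3: {"first": 1.0, "t2_11": 1.5, "t12_21": 1.75, "t22_31": 2.0},
        }
        table = {(condition, s, b): (0.0, f[s][b]) for s in f for b in BINS}
        return cls(table=table)


def _unique_geodesic_fraction(maze: MazeGraph, starts, goal) -> float:
    return sum(1 for s in starts if len(maze.geodesics(s, goal)) == 1) / len(starts)


def check_protocol(protocol: ProtocolSpec, maze: MazeGraph):
    """Raise :class:`GenerationError` if any protocol invariant is violated."""
    prev_first = prev_last = None
    for k, sess in enumerate(protocol.sessions, start=1):
        m = build_hexmaze(sess.barrier_edges) if sess.barrier_edges else maze
        starts = sess.starts
        if not starts:
            raise GenerationError(f"session {k} has no starts")
        for i, s in enumerate(starts):
            if s == sess.goal or m.distance(s, sess.goal) < MIN_SEPARATION:
                raise GenerationError(f"session {k} trial {i + 1}: start {s} too close to goal")
            if i and (s == starts[i - 1] or m.distance(s, starts[i - 1]) < MIN_SEPARATION):
                raise GenerationError(f"session {k} trial {i + 1}: start {s} too close to "
                                      f"previous start {starts[i - 1]}")
        if prev_first is not None and starts[0] in (prev_first, prev_last):
            raise GenerationError(f"session {k}: first start repeats previous session's "
                                  "first or last start")
        frac = _unique_geodesic_fraction(m, starts, sess.goal)
        if frac < UNIQUE_GEODESIC_MIN:
            raise GenerationError(f"session {k}: unique-geodesic fraction {frac:.2f} < "
                                  f"{UNIQUE_GEODESIC_MIN}")
        prev_first, prev_last = starts[0], starts[-1]


def _sample_session_starts(maze: MazeGraph, goal: int, n_trials: int, rng,
                           forbidden_first) -> Optional[tuple]:
    """One attempt at a start sequence; None if it dead-ends or fails the
    unique-geodesic quota."""
    eligible = [v for v in maze.nodes
                if v != goal and maze.distance(v, goal) >= MIN_SEPARATION]
    unique = {v for v in eligible if len(maze.geodesics(v, goal)) == 1}
    starts = []
    for i in range(n_trials):
        cand = eligible
        if i == 0:
            cand = [v for v in cand if v not in forbidden_first]
        else:
            prev = starts[-1]
            cand = [v for v in cand if v != prev and maze.distance(v, prev) >= MIN_SEPARATION]
        if not cand:
            return None
        # bias toward unique-geodesic starts so the 60% quota is met reliably
        uniq_cand = [v for v in cand if v in unique]
        if uniq_cand and rng.random() < 0.75:
            starts.append(uniq_cand[rng.integers(0, len(uniq_cand))])
        else:
            starts.append(cand[rng.integers(0, len(cand))])
    if _unique_geodesic_fraction(maze, starts, goal) < UNIQUE_GEODESIC_MIN:
        return None
    return tuple(starts)


def _sample_barriers(base: MazeGraph, goal: int, rng, max_attempts: int = 1000):
    """1-3 removable edges keeping the maze connected; paired with a check
    that they reroute the goal's geodesics from at least half the starts."""
    edges = sorted(tuple(sorted(e)) for e in base.graph.edges)
    for _ in range(max_attempts):
        k = int(rng.integers(1, 4))
        idx = rng.choice(len(edges), size=k, replace=False)
        barriers = tuple(edges[i] for i in sorted(idx))
        try:
            m = build_hexmaze(barriers)
        except Exception:
            continue
        return barriers, m
    raise GenerationError("could not sample a connected barrier configuration")


def _barriers_change_paths(base: MazeGraph, barriered: MazeGraph, starts, goal) -> bool:
    changed = sum(
        1 for s in starts
        if barriered.optimal_path_set(s, goal).nodes != base.optimal_path_set(s, goal).nodes)
    return changed >= 0.5 * len(starts)


def generate_protocol(maze: MazeGraph, condition: str, n_sessions: int = 3,
                      trials_per_session: int = 31, rng=None,
                      goal_ring: Optional[str] = None) -> ProtocolSpec:
    """Rejection-sample a protocol satisfying all start-location rules.

    ``goal_ring`` forces the goal onto the inner or outer ring; by default
    the goal is drawn with the experiment's 1-in-4 inner-ring odds.
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    rng = as_generator(rng)
    if goal_ring is None:
        goal_ring = "inner" if rng.random() < 0.25 else "outer"
    pool = maze.inner_nodes if goal_ring == "inner" else maze.outer_nodes
    goal = int(pool[rng.integers(0, len(pool))])

    session_maze = maze
    barriers = ()
    sessions = []
    prev_first = prev_last = None
    for k in range(n_sessions):
        forbidden = {prev_first, prev_last} - {None}
        for attempt in range(MAX_SESSION_ATTEMPTS):
            if condition == "barrier_update" and (k == 0 or not barriers):
                barriers, session_maze = _sample_barriers(maze, goal, rng)
            starts = _sample_session_starts(session_maze, goal, trials_per_session,
                                            rng, forbidden)
            if starts is None:
                continue
            if condition == "barrier_update" and k == 0 and not _barriers_change_paths(
                    maze, session_maze, starts, goal):
                barriers = ()
                continue
            break
        else:
            raise GenerationError(
                f"session {k + 1}: no start sequence found in {MAX_SESSION_ATTEMPTS} "
                f"attempts (condition={condition}, goal={goal})")
        sessions.append(SessionSpec(goal=goal, starts=starts, barrier_edges=barriers))
        prev_first, prev_last = starts[0], starts[-1]
    protocol = ProtocolSpec(condition=condition, sessions=tuple(sessions),
                            trials_per_session=trials_per_session)
    check_protocol(protocol, maze)
    return protocol


def generate_dataset(maze: MazeGraph, schedule: GroundTruthSchedule,
                     n_animals: int, rng=None, condition: str = "build_up",
                     protocol: Optional[ProtocolSpec] = None,
                     trials_per_session: int = 31, n_sessions: int = 3,
                     max_steps: int = 5000) -> tuple:
    """Simulate a labeled dataset at the schedule's known (eta, F).

    One protocol per animal (goal rings counterbalanced 1-in-4 inner) unless
    an explicit ``protocol`` is shared by all.  Returns ``(trials, truth)``
    where ``truth`` records the schedule and the per-animal protocols.
    """
    if n_animals < 1:
        raise ParameterError("n_animals must be >= 1")
    rng = as_generator(rng)
    trials = []
    protocols = {}
    maze_cache = {(): maze}
    for a in range(n_animals):
        animal = f"a{a + 1}"
        if protocol is None:
            ring = "inner" if a % 4 == 3 else "outer"
            proto = generate_protocol(maze, condition, n_sessions=n_sessions,
                                      trials_per_session=trials_per_session,
                                      rng=rng, goal_ring=ring)
        else:
            proto = protocol
        protocols[animal] = proto
        for s_idx, sess in enumerate(proto.sessions, start=1):
            key = tuple(sess.barrier_edges)
            if key not in maze_cache:
                maze_cache[key] = build_hexmaze(key)
            m = maze_cache[key]
            for t_idx, start in enumerate(sess.starts, start=1):
                b = trial_bin(t_idx)
                if b is None:
                    continue
                eta, f = schedule.params(proto.condition, s_idx, b)
                params = SimParams(eta=eta, foresight=f, max_steps=max_steps)
                trials.append(simulate_trial(
                    m, start, sess.goal, params, rng=rng,
                    animal_id=animal, condition=proto.condition,
                    session=s_idx, trial_index=t_idx))
    truth = {"schedule": schedule, "protocols": protocols}
    return trials, truth
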