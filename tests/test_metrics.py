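"""RTL, DFOP, trial grouping, shuffle surrogates and bootstrap summaries."""

import math

import numpy as np
import pytest

from hexnav import (DegenerateTrialError, ParameterError, SimParams, Trajectory,
                    bootstrap_summary, dfop_profile, dfop_series, gl_shuffle,
                    group_trials, node_crossings, optimal_path_set_exact,
                    optimal_trial_probability, relative_trial_length,
                    simulate_trial, trial_bin)


def make_walk(maze, start, n_steps, rng, goal=None, **meta):
    """A random no-reversal walk of fixed length, ending where it ends."""
    nodes = [start]
    prev = None
    for _ in range(n_steps):
        cand = [w for w in maze.neighbors(nodes[-1]) if w != prev]
        prev = nodes[-1]
        nodes.append(cand[rng.integers(0, len(cand))])
    goal = nodes[-1] if goal is None else goal
    return Trajectory(nodes=tuple(nodes), goal=goal,
                      completed=nodes[-1] == goal and goal not in nodes[:-1], **meta)


def geodesic_trial(maze, start, goal, **meta):
    return Trajectory(nodes=maze.geodesics(start, goal)[0], goal=goal, **meta)


class TestRTL:
    def test_geodesic_scores_one(self, maze):
        t = geodesic_trial(maze, 7, 13)
        m = relative_trial_length(t, maze)
        assert m.rtl == 1.0
        assert m.log_rtl == 0.0
        assert m.max_dfop == 0

    def test_doubled_path_scores_two(self, maze):
        # out-and-back detour on the outer ring then the direct run 7->1->2
        t = Trajectory(nodes=(7, 8, 7, 1, 2), goal=2)
        m = relative_trial_length(t, maze)
        assert maze.distance(7, 2) == 2
        assert m.rtl == 2.0
        assert m.path_steps == 4

    def test_hand_counted_nine_step_walk(self, maze):
        # 9 edges traversed to a goal 3 edges away: RTL = 3 by hand count
        walk = (7, 8, 9, 8, 7, 24, 7, 1, 2, 3)
        t = Trajectory(nodes=walk, goal=3)
        assert maze.distance(7, 3) == 3
        m = relative_trial_length(t, maze)
        assert m.rtl == pytest.approx(3.0)
        assert m.log_rtl == pytest.approx(math.log10(3.0))

    def test_start_equals_goal_rejected(self, maze):
        with pytest.raises(DegenerateTrialError):
            relative_trial_length(Trajectory(nodes=(7,), goal=7), maze)

    def test_incomplete_trial_rejected(self, maze):
        t = Trajectory(nodes=(7, 8, 9), goal=13, completed=False)
        with pytest.raises(DegenerateTrialError):
            relative_trial_length(t, maze)

    def test_outer_and_inner_fractions_partition(self, maze, rng):
        for _ in range(20):
            t = make_walk(maze, 7, 15, rng)
            m_out = relative_trial_length(t, maze) if t.completed else None
            nodes = t.nodes
            outer = sum(1 for v in nodes if maze.ring[v] == "outer")
            inner = sum(1 for v in nodes if maze.ring[v] == "inner")
            assert outer + inner == len(nodes)


class TestDFOP:
    def test_geodesic_all_zeros(self, maze):
        t = geodesic_trial(maze, 7, 16)
        assert dfop_series(t, maze) == [0] * (maze.distance(7, 16) + 1)

    def test_single_detour_node(self, maze):
        # 7 -> 24 is one step off the 7->2 geodesics; then back and through
        t = Trajectory(nodes=(7, 24, 7, 1, 2), goal=2)
        series = dfop_series(t, maze)
        assert series[0] == 0 and series[-1] == 0
        assert series.count(1) == 1 and max(series) == 1

    def test_matches_bruteforce_over_geodesic_nodes(self, maze, rng):
        for _ in range(25):
            t = make_walk(maze, int(rng.choice(maze.nodes)), 12, rng)
            opt = optimal_path_set_exact(maze, t.start, t.goal)
            # the series covers the walk up to the first goal arrival
            upto = t.nodes[: t.nodes.index(t.goal) + 1]
            expected = [min(maze.distance(v, w) for w in opt.nodes) for v in upto]
            assert dfop_series(t, maze) == expected

    def test_max_dfop_consistency(self, maze, rng):
        for _ in range(10):
            t = make_walk(maze, 7, 20, rng)
            if not t.completed:
                continue
            m = relative_trial_length(t, maze)
            assert m.max_dfop == max(dfop_series(t, maze))


class TestDFOPProfile:
    def test_all_geodesic_group_is_flat_zero(self, maze):
        trials = [geodesic_trial(maze, s, g) for s, g in [(7, 13), (8, 20), (1, 16)]]
        prof = dfop_profile(trials, maze, horizon=4)
        assert np.all(prof.mean == 0)

    def test_single_trial_profile_equals_its_series(self, maze, rng):
        t = make_walk(maze, 7, 10, rng)
        series = dfop_series(t, maze)
        prof = dfop_profile([t], maze, horizon=len(series) - 1, pad=False)
        assert list(prof.mean) == series
        assert np.all(prof.sd == 0)

    def test_padding_extends_with_zeros(self, maze):
        t = geodesic_trial(maze, 7, 13)
        prof = dfop_profile([t], maze, horizon=10, pad=True)
        assert prof.mean.shape == (11,)
        assert np.all(prof.mean == 0) and np.all(prof.n == 1)
        unpadded = dfop_profile([t], maze, horizon=10, pad=False)
        assert unpadded.n[-1] == 0 and np.isnan(unpadded.mean[-1])

    def test_random_search_group_shows_bump(self, maze, rng):
        # memoryless searchers (F=0) stray then converge: rise-then-fall mean
        trials = [simulate_trial(maze, 7, 16, SimParams(), rng=rng) for _ in range(300)]
        prof = dfop_profile([t for t in trials if t.completed], maze)
        peak = int(np.nanargmax(prof.mean))
        assert prof.mean[0] == 0
        assert prof.mean[peak] > 0.5
        assert 0 < peak < prof.horizon
        assert prof.mean[peak] > prof.mean[-1]

    def test_empty_group_rejected(self, maze):
        with pytest.raises(ParameterError):
            dfop_profile([], maze)


class TestOptimalTrialProbability:
    def test_counting(self, maze, rng):
        fast = [geodesic_trial(maze, 7, 13) for _ in range(3)]
        slow = [Trajectory(nodes=(7, 8, 9, 8, 7, 1, 2), goal=2)]  # rtl = 3
        frac, sd = optimal_trial_probability(fast + slow, maze, rng=rng)
        assert frac == pytest.approx(3 / 4)
        assert sd >= 0
        assert optimal_trial_probability(fast, maze, rng=rng)[0] == 1.0
        assert optimal_trial_probability(slow * 2, maze, rng=rng)[0] == 0.0


class TestGLShuffle:
    def test_absent_surrogate_goal_scores_ten(self, maze):
        # two geodesic trials whose goals never appear in each other's path:
        # whenever the shuffle swaps them, both surrogate RTLs default to 10
        t1 = geodesic_trial(maze, 7, 9)    # along outer ring
        t2 = geodesic_trial(maze, 16, 18)  # opposite side
        assert t2.goal not in t1.nodes and t1.goal not in t2.nodes
        swapped = None
        for seed in range(50):
            mets = gl_shuffle([t1, t2], maze, rng=seed)
            if mets[0].rtl != 1.0:  # non-identity permutation
                swapped = mets
                break
        assert swapped is not None
        assert [m.rtl for m in swapped] == [10.0, 10.0]

    def test_identical_goals_leave_metrics_unchanged(self, maze, rng):
        trials = [geodesic_trial(maze, s, 13) for s in (7, 9, 20)]
        mets = gl_shuffle(trials, maze, rng=rng)
        orig = [relative_trial_length(t, maze) for t in trials]
        assert sorted(m.rtl for m in mets) == sorted(o.rtl for o in orig)

    def test_visited_surrogate_goal_hand_count(self, maze):
        # trial A runs 7->1->2 (goal 2); trial B starts at 8 with goal 1.
        # A's surrogate goal 1 sits one step in: sub-path 7->1, d(7,1)=1, RTL=1.
        a = Trajectory(nodes=(7, 1, 2), goal=2)
        b = Trajectory(nodes=(8, 7, 1), goal=1)
        found = False
        for seed in range(20):
            mets = gl_shuffle([a, b], maze, rng=seed)
            if mets[0].rtl != relative_trial_length(a, maze).rtl or True:
                # identify the non-identity permutation: a gets goal 1
                if any(m.rtl == 1.0 and m.path_steps == 1 for m in mets):
                    found = True
                    break
        assert found

    def test_too_few_trials_rejected(self, maze):
        with pytest.raises(ParameterError):
            gl_shuffle([geodesic_trial(maze, 7, 13)], maze, rng=0)


class TestNodeCrossings:
    def test_counts_match_naive_scan(self, maze, rng):
        t = make_walk(maze, 7, 30, rng)
        counts = node_crossings(t, set(maze.nodes))
        for v in maze.nodes:
            assert counts[v] == sum(1 for w in t.nodes if w == v)
        assert counts[t.start] >= 1
        absent = [v for v in maze.nodes if v not in t.nodes]
        if absent:
            assert counts[absent[0]] == 0


class TestBootstrapSummary:
    def test_constant_vector_has_zero_sd(self, rng):
        mean, sd = bootstrap_summary([2.5] * 10, rng=rng)
        assert mean == pytest.approx(2.5)
        assert sd == 0.0

    def test_mean_close_to_arithmetic_mean(self, rng):
        vals = rng.normal(5.0, 1.0, size=200)
        mean, sd = bootstrap_summary(vals, rng=rng)
        assert mean == pytest.approx(np.mean(vals), abs=4 * np.std(vals) / np.sqrt(200))

    def test_matches_independent_resampling_loop(self):
        vals = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        seed = 99
        mean, sd = bootstrap_summary(vals, n_boot=50, rng=np.random.default_rng(seed))
        # independent re-implementation: same draws, hand-rolled statistics
        rng2 = np.random.default_rng(seed)
        idx = rng2.integers(0, len(vals), size=(50, len(vals)))
        means = [sum(vals[i] for i in row) / len(row) for row in idx]
        assert mean == pytest.approx(sum(means) / 50)
        assert sd == pytest.approx(math.sqrt(sum((m - sum(means) / 50) ** 2 for m in means) / 50))

    def test_empty_rejected(self, rng):
        with pytest.raises(ParameterError):
            bootstrap_summary([], rng=rng)


class TestTrialGrouping:
    @pytest.mark.parametrize("idx,expected", [
        (1, "first"), (2, "t2_11"), (11, "t2_11"), (12, "t12_21"),
        (21, "t12_21"), (22, "t22_31"), (31, "t22_31"), (32, None),
    ])
    def test_bin_boundaries(self, idx, expected):
        assert trial_bin(idx) == expected

    def test_group_trials_drops_beyond_31(self, maze):
        trials = [Trajectory(nodes=(7, 1), goal=1, trial_index=i) for i in (1, 5, 32)]
        groups = group_trials(trials)
        total = sum(len(v) for v in groups.values())
        assert total == 2
        assert ("build_up", 1, "first") in groups
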