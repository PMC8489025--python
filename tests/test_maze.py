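"""Maze construction, distances and geodesic-set enumeration."""

import itertools
from collections import Counter, deque

import networkx as nx
import numpy as np
import pytest

from hexnav import (MazeConfigurationError, ParameterError, build_hexmaze,
                    graph_distance, load_maze, optimal_path_set_exact,
                    optimal_path_set_noisy, save_maze)


def bfs_distances(adj, source):
    """Plain breadth-first distances, independent of networkx."""
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def enumerate_shortest_path_nodes(adj, dist_from, start, goal):
    """Union of nodes on all shortest paths, by depth-first enumeration."""
    target = dist_from[start][goal]
    nodes = set()

    def dfs(v, path):
        if v == goal:
            nodes.update(path)
            return
        for w in adj[v]:
            if len(path) + dist_from[w][goal] <= target:
                dfs(w, path + [w])

    dfs(start, [start])
    return nodes


@pytest.fixture(scope="module")
def adj(maze):
    return {v: list(maze.neighbors(v)) for v in maze.nodes}


@pytest.fixture(scope="module")
def all_bfs(maze, adj):
    return {v: bfs_distances(adj, v) for v in maze.nodes}


class TestStructure:
    def test_node_and_edge_counts(self, maze):
        assert len(maze.nodes) == 24
        assert maze.graph.number_of_edges() == 30

    def test_degree_split(self, maze):
        degs = Counter(d for _, d in maze.graph.degree)
        assert degs == {2: 12, 3: 12}

    def test_rings_partition_nodes(self, maze):
        inner, outer = set(maze.inner_nodes), set(maze.outer_nodes)
        assert len(inner) == 6 and len(outer) == 18
        assert inner | outer == set(maze.nodes)
        assert not inner & outer

    def test_rings_are_cycles(self, maze):
        for ring, n in ((maze.inner_nodes, 6), (maze.outer_nodes, 18)):
            sub = maze.graph.subgraph(ring)
            assert sub.number_of_edges() == n
            assert all(d == 2 for _, d in sub.degree)

    def test_inner_ring_nodes_are_three_way(self, maze):
        assert all(maze.graph.degree[v] == 3 for v in maze.inner_nodes)

    def test_bipartite_and_connected(self, maze):
        assert nx.is_connected(maze.graph)
        assert nx.is_bipartite(maze.graph)

    def test_coordinates_respect_edge_length(self, maze):
        from hexnav import EDGE_LENGTH_CM
        for u, v in maze.graph.edges:
            (x1, y1), (x2, y2) = maze.coords[u], maze.coords[v]
            assert np.hypot(x1 - x2, y1 - y2) == pytest.approx(EDGE_LENGTH_CM, rel=1e-3)


class TestBarriers:
    def test_barrier_removes_edge(self, maze):
        edge = next(iter(maze.graph.edges))
        m = build_hexmaze(barrier_edges=[edge])
        assert not m.has_edge(*edge)
        assert m.graph.number_of_edges() == 29

    def test_isolating_barriers_rejected(self, maze):
        v = maze.nodes[0]
        barriers = [(v, w) for w in maze.neighbors(v)]
        with pytest.raises(MazeConfigurationError, match="disconnect"):
            build_hexmaze(barrier_edges=barriers)

    def test_nonexistent_edge_rejected(self, maze):
        a = maze.nodes[0]
        far = max(maze.nodes, key=lambda v: maze.distance(a, v))
        with pytest.raises(MazeConfigurationError, match="not a maze edge"):
            build_hexmaze(barrier_edges=[(a, far)])

    def test_barriered_maze_distances_grow(self, maze):
        edge = next(iter(maze.graph.edges))
        m = build_hexmaze(barrier_edges=[edge])
        u, v = edge
        assert m.distance(u, v) > 1


class TestDistance:
    def test_identity_and_adjacency(self, maze):
        v = maze.nodes[0]
        assert graph_distance(maze, v, v) == 0
        assert all(graph_distance(maze, v, w) == 1 for w in maze.neighbors(v))

    def test_matches_bfs_oracle_all_pairs(self, maze, all_bfs):
        for a in maze.nodes:
            for b in maze.nodes:
                assert maze.distance(a, b) == all_bfs[a][b]

    def test_diameter_from_oracle(self, maze, all_bfs):
        oracle = max(max(row.values()) for row in all_bfs.values())
        assert maze.diameter == oracle

    def test_symmetry_and_triangle_inequality(self, maze, rng):
        nodes = maze.nodes
        for _ in range(200):
            a, b, c = rng.choice(nodes, size=3)
            assert maze.distance(a, b) == maze.distance(b, a)
            assert maze.distance(a, c) <= maze.distance(a, b) + maze.distance(b, c)

    def test_unknown_node_raises(self, maze):
        with pytest.raises(KeyError):
            maze.distance(1, 99)


class TestOptimalPathSet:
    def test_trivial_cases(self, maze):
        v = maze.nodes[0]
        w = maze.neighbors(v)[0]
        assert optimal_path_set_exact(maze, v, v).nodes == {v}
        assert optimal_path_set_exact(maze, v, v).distance == 0
        assert optimal_path_set_exact(maze, v, w).nodes == {v, w}

    def test_matches_dfs_enumeration_all_pairs(self, maze, adj, all_bfs):
        for a, b in itertools.permutations(maze.nodes, 2):
            expected = enumerate_shortest_path_nodes(adj, all_bfs, a, b)
            got = optimal_path_set_exact(maze, a, b)
            assert got.nodes == expected
            # every member lies on some geodesic
            assert all(all_bfs[a][v] + all_bfs[v][b] == got.distance for v in got.nodes)

    def test_noisy_converges_to_exact(self, maze, rng):
        for a, b in [(7, 13), (1, 4), (8, 20), (7, 16)]:
            exact = optimal_path_set_exact(maze, a, b)
            noisy = optimal_path_set_noisy(maze, a, b, n_reps=200, rng=rng)
            assert noisy.nodes == exact.nodes
            assert noisy.distance == exact.distance

    def test_single_rep_gives_one_geodesic(self, maze, rng):
        a, b = 7, 16
        exact = optimal_path_set_exact(maze, a, b)
        single = optimal_path_set_noisy(maze, a, b, n_reps=1, rng=rng)
        assert single.nodes <= exact.nodes
        assert len(single.nodes) == exact.distance + 1  # one path's worth of nodes

    def test_unique_geodesic_pair_exact_for_any_reps(self, maze, rng):
        # find a pair with a unique geodesic
        pair = next((a, b) for a, b in itertools.permutations(maze.nodes, 2)
                    if len(maze.geodesics(a, b)) == 1 and maze.distance(a, b) >= 3)
        exact = optimal_path_set_exact(maze, *pair)
        assert optimal_path_set_noisy(maze, *pair, n_reps=1, rng=rng).nodes == exact.nodes

    def test_excessive_noise_rejected(self, maze, rng):
        with pytest.raises(ParameterError):
            optimal_path_set_noisy(maze, 7, 13, noise_scale=0.5, rng=rng)


class TestSerialization:
    def test_round_trip(self, maze, tmp_path):
        path = tmp_path / "maze_edges.txt"
        save_maze(maze, path)
        loaded = load_maze(path)
        assert set(loaded.graph.edges) == set(maze.graph.edges)
        assert loaded.ring == maze.ring
        assert loaded.coords == {v: tuple(c) for v, c in maze.coords.items()}

    def test_loader_validates(self, maze, tmp_path):
        path = tmp_path / "maze_edges.txt"
        save_maze(maze, path)
        text = path.read_text().splitlines()
        path.write_text("\n".join(text[:-1]) + "\n")  # drop one edge
        with pytest.raises(MazeConfigurationError):
            load_maze(path)
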