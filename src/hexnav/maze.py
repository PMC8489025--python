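"""The HexMaze graph: construction, geodesics and ring structure.

The maze is a "flower" of seven regular hexagons — six hexagonal modules
packed around a central hexagonal circuit.  Its 24 intersection nodes are
joined by 30 gangways (edges), forming twelve two-way and twelve three-way
choice points.  The six nodes of the central circuit make up the *inner
ring*; the remaining 18 boundary nodes form the *outer ring*.

Node numbering convention (the physical maze's own numbering is not
published, so any consistent labelling is admissible): nodes 1-6 are the
inner ring, counter-clockwise starting due east; nodes 7-24 are the outer
ring, counter-clockwise with node 7 due east.  Spokes join node ``k`` of the
inner ring to outer node ``7 + 3*(k-1)``.

All analysis distances are measured in edges; planar coordinates (cm, edge
length 36.3 cm) are carried only for plotting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import networkx as nx

from ._util import as_generator
from .errors import MazeConfigurationError, ParameterError

#: centre-to-centre distance between adjacent intersections, in cm
EDGE_LENGTH_CM = 36.3

N_NODES = 24
N_EDGES = 30


def _flower_vertices(side: float = EDGE_LENGTH_CM):
    """Vertices and edges of the seven-hexagon flower, from plane geometry."""
    centers = [(0.0, 0.0)]
    for k in range(6):
        a = math.radians(30 + 60 * k)
        centers.append((math.sqrt(3) * side * math.cos(a), math.sqrt(3) * side * math.sin(a)))
    g = nx.Graph()
    for cx, cy in centers:
        verts = []
        for k in range(6):
            a = math.radians(60 * k)
            verts.append((round(cx + side * math.cos(a), 3), round(cy + side * math.sin(a), 3)))
        for i in range(6):
            g.add_edge(verts[i], verts[(i + 1) % 6])
    return g


def _angle(p) -> float:
    a = round(math.atan2(p[1], p[0]), 9)
    return a + 2 * math.pi if a < 0 else a


@dataclass(frozen=True)
class OptimalPathSet:
    """All nodes lying on at least one shortest ``start`` → ``goal`` path."""

    start: int
    goal: int
    nodes: frozenset
    distance: int

    def __contains__(self, v) -> bool:
        return v in self.nodes


class MazeGraph:
    """Undirected HexMaze graph with ring labels and planar coordinates.

    Gangways are physically bidirectional, so the graph is stored
    undirected; the no-reversal rule of real and simulated trajectories is a
    property of the walker, not of the maze.  Barriers are modelled purely
    as edge removals and must leave the maze connected.
    """

    def __init__(self, graph: nx.Graph, ring: dict, coords: dict,
                 removed_edges: frozenset = frozenset()):
        self.graph = graph
        self.ring = dict(ring)
        self.coords = dict(coords)
        self.removed_edges = frozenset(frozenset(e) for e in removed_edges)
        self._dist = dict(nx.all_pairs_shortest_path_length(graph))
        self._neighbors = {v: tuple(sorted(graph[v])) for v in graph}
        self._geodesics = {}

    # -- basic structure ---------------------------------------------------
    @property
    def nodes(self) -> tuple:
        return tuple(sorted(self.graph.nodes))

    @property
    def inner_nodes(self) -> tuple:
        return tuple(v for v in self.nodes if self.ring[v] == "inner")

    @property
    def outer_nodes(self) -> tuple:
        return tuple(v for v in self.nodes if self.ring[v] == "outer")

    def neighbors(self, v) -> tuple:
        self._check_node(v)
        return self._neighbors[v]

    def has_edge(self, a, b) -> bool:
        return self.graph.has_edge(a, b)

    @property
    def diameter(self) -> int:
        return max(max(row.values()) for row in self._dist.values())

    def _check_node(self, v):
        if v not in self._dist:
            raise KeyError(f"node {v!r} is not in the maze")

    # -- distances and geodesics ------------------------------------------
    def distance(self, a, b) -> int:
        """Shortest-path length between ``a`` and ``b``, in edges."""
        self._check_node(a)
        self._check_node(b)
        return self._dist[a][b]

    def geodesics(self, a, b) -> tuple:
        """All shortest ``a`` → ``b`` paths, each a tuple of nodes (cached)."""
        self._check_node(a)
        self._check_node(b)
        key = (a, b)
        paths = self._geodesics.get(key)
        if paths is None:
            paths = tuple(tuple(p) for p in nx.all_shortest_paths(self.graph, a, b))
            self._geodesics[key] = paths
        return paths

    def optimal_path_set(self, start, goal) -> OptimalPathSet:
        """Exact geodesic-node set via distances from both endpoints.

        A node ``v`` lies on some shortest path iff
        ``d(start, v) + d(v, goal) == d(start, goal)``.
        """
        self._check_node(start)
        self._check_node(goal)
        d = self._dist[start][goal]
        ds, dg = self._dist[start], self._dist[goal]
        members = frozenset(v for v in self._dist if ds[v] + dg[v] == d)
        return OptimalPathSet(start=start, goal=goal, nodes=members, distance=d)

    def optimal_path_set_noisy(self, start, goal, n_reps: int = 100,
                               noise_scale: float = 1e-3, rng=None) -> OptimalPathSet:
        """Geodesic-node set by repeated noisy-weight shortest-path search.

        Edge weights are initialised at 1 and perturbed with independent
        Uniform(0, noise_scale) noise; with equal-length alternatives, each
        perturbation singles out one of them at random, and the union over
        repetitions collects every geodesic node.  ``noise_scale`` must stay
        below ``1 / n_edges`` so noise can never promote a longer path.
        """
        if n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        n_edges = self.graph.number_of_edges()
        if not 0 < noise_scale < 1.0 / n_edges:
            raise ParameterError(
                f"noise_scale must be in (0, 1/{n_edges}) so geodesics cannot flip")
        self._check_node(start)
        self._check_node(goal)
        rng = as_generator(rng)
        edges = list(self.graph.edges)
        members = set()
        for _ in range(n_reps):
            noise = rng.uniform(0.0, noise_scale, size=len(edges))
            w = {e: 1.0 + x for e, x in zip(edges, noise)}
            nx.set_edge_attributes(self.graph, w, "weight")
            members.update(nx.shortest_path(self.graph, start, goal, weight="weight"))
        for e in edges:  # leave the graph unweighted
            del self.graph.edges[e]["weight"]
        return OptimalPathSet(start=start, goal=goal, nodes=frozenset(members),
                              distance=self._dist[start][goal])

    # -- validation --------------------------------------------------------
    def check_invariants(self, base: bool = True):
        """Assert structural invariants; ``base=False`` skips exact counts
        (for barriered variants, which only need connectivity and rings)."""
        g = self.graph
        if not nx.is_connected(g):
            raise MazeConfigurationError("maze graph is disconnected")
        if not nx.is_bipartite(g):
            raise MazeConfigurationError("maze graph is not bipartite")
        inner, outer = set(self.inner_nodes), set(self.outer_nodes)
        if inner | outer != set(g.nodes) or inner & outer:
            raise MazeConfigurationError("ring labels do not partition the nodes")
        if base:
            if g.number_of_nodes() != N_NODES or g.number_of_edges() != N_EDGES:
                raise MazeConfigurationError(
                    f"expected {N_NODES} nodes / {N_EDGES} edges, got "
                    f"{g.number_of_nodes()} / {g.number_of_edges()}")
            degs = sorted(d for _, d in g.degree)
            if degs != [2] * 12 + [3] * 12:
                raise MazeConfigurationError("expected 12 two-way and 12 three-way nodes")
            if len(inner) != 6 or len(outer) != 18:
                raise MazeConfigurationError("expected 6 inner and 18 outer nodes")
            for ring, n in ((inner, 6), (outer, 18)):
                sub = g.subgraph(ring)
                if sub.number_of_edges() != n or any(d != 2 for _, d in sub.degree):
                    raise MazeConfigurationError("ring is not a simple cycle")


@lru_cache(maxsize=1)
def _base_layout():
    """Canonical node numbering, coordinates, ring labels and edge list."""
    geo = _flower_vertices()
    inner = sorted((v for v in geo if math.hypot(*v) < 1.5 * EDGE_LENGTH_CM), key=_angle)
    outer = sorted((v for v in geo if math.hypot(*v) >= 1.5 * EDGE_LENGTH_CM), key=_angle)
    label = {v: i + 1 for i, v in enumerate(inner)}
    label.update({v: i + 7 for i, v in enumerate(outer)})
    edges = tuple(sorted(tuple(sorted((label[a], label[b]))) for a, b in geo.edges))
    coords = {label[v]: v for v in geo}
    ring = {label[v]: ("inner" if v in set(inner) else "outer") for v in geo}
    return edges, ring, coords


def build_hexmaze(barrier_edges=None) -> MazeGraph:
    """Construct the HexMaze, optionally with barrier edges removed.

    Parameters
    ----------
    barrier_edges : iterable of (u, v) pairs, optional
        Gangways blocked by barriers.  Each pair must be an existing edge,
        and the maze must stay connected after removal.
    """
    edges, ring, coords = _base_layout()
    g = nx.Graph(edges)
    removed = frozenset()
    if barrier_edges:
        removed = frozenset(frozenset(e) for e in barrier_edges)
        for e in removed:
            u, v = tuple(e)
            if not g.has_edge(u, v):
                raise MazeConfigurationError(f"barrier {tuple(sorted((u, v)))} is not a maze edge")
        g.remove_edges_from(tuple(e) for e in removed)
        if not nx.is_connected(g):
            bad = sorted(tuple(sorted(e)) for e in removed)
            raise MazeConfigurationError(f"barriers {bad} disconnect the maze")
    maze = MazeGraph(g, ring, coords, removed_edges=removed)
    maze.check_invariants(base=not barrier_edges)
    return maze


# -- functional aliases matching the public vocabulary ----------------------

def graph_distance(g: MazeGraph, a, b) -> int:
    """Shortest-path length between two nodes, in edges."""
    return g.distance(a, b)


def optimal_path_set_exact(g: MazeGraph, start, goal) -> OptimalPathSet:
    """Exact geodesic-node set between ``start`` and ``goal``."""
    return g.optimal_path_set(start, goal)


def optimal_path_set_noisy(g: MazeGraph, start, goal, n_reps: int = 100,
                           noise_scale: float = 1e-3, rng=None) -> OptimalPathSet:
    """Noisy-weight geodesic-node set (validation variant of the exact set)."""
    return g.optimal_path_set_noisy(start, goal, n_reps=n_reps,
                                    noise_scale=noise_scale, rng=rng)


# -- serialization -----------------------------------------------------------

def save_maze(maze: MazeGraph, edge_path, meta_path=None):
    """Write the maze as an edge list (one ``u v`` per line) + JSON sidecar."""
    edge_path = Path(edge_path)
    meta_path = Path(meta_path) if meta_path else edge_path.with_suffix(".json")
    lines = [f"{u} {v}" for u, v in sorted(tuple(sorted(e)) for e in maze.graph.edges)]
    edge_path.write_text("\n".join(lines) + "\n")
    meta = {
        "ring": {str(v): r for v, r in sorted(maze.ring.items())},
        "coords": {str(v): list(maze.coords[v]) for v in sorted(maze.coords)},
        "removed_edges": sorted(sorted(e) for e in maze.removed_edges),
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def load_maze(edge_path, meta_path=None) -> MazeGraph:
    """Read a maze written by :func:`save_maze`, validating invariants."""
    edge_path = Path(edge_path)
    meta_path = Path(meta_path) if meta_path else edge_path.with_suffix(".json")
    g = nx.Graph()
    for i, line in enumerate(edge_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MazeConfigurationError(f"{edge_path}:{i}: expected 'u v', got {line!r}")
        g.add_edge(int(parts[0]), int(parts[1]))
    meta = json.loads(meta_path.read_text())
    ring = {int(k): v for k, v in meta["ring"].items()}
    coords = {int(k): tuple(v) for k, v in meta["coords"].items()}
    removed = frozenset(frozenset(e) for e in meta.get("removed_edges", []))
    maze = MazeGraph(g, ring, coords, removed_edges=removed)
    maze.check_invariants(base=not removed)
    return maze
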