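"""Build the HexMaze graph and inspect its structure.

The maze is a flower of seven hexagons: 24 intersection nodes (choice
points) joined by 30 gangways.  Twelve nodes are two-way and twelve are
three-way choice points; the six central nodes form the inner ring, the 18
boundary nodes the outer ring.  All distances are counted in edges.
"""

from collections import Counter

from hexnav import build_hexmaze, optimal_path_set_exact, optimal_path_set_noisy

maze = build_hexmaze()

print(f"nodes: {len(maze.nodes)}, gangways: {maze.graph.number_of_edges()}")
print("choice-point split:", dict(Counter(d for _, d in maze.graph.degree)))
print("inner ring:", maze.inner_nodes)
print("outer ring:", maze.outer_nodes)
print("diameter:", maze.diameter, "edges")

start, goal = 7, 16  # opposite corners of the maze
opt = optimal_path_set_exact(maze, start, goal)
print(f"\nshortest {start} -> {goal}: {opt.distance} edges")
print("nodes on some shortest path:", sorted(opt.nodes))
print("all geodesics:", [list(p) for p in maze.geodesics(start, goal)])

# the noisy-weight variant re-derives the same set by repeatedly perturbing
# edge weights and collecting whichever geodesic wins each time
noisy = optimal_path_set_noisy(maze, start, goal, n_reps=200, rng=0)
print("noisy-weight enumeration agrees with the exact set:", noisy.nodes == opt.nodes)

# barriers are edge removals; the maze must stay connected
barriered = build_hexmaze(barrier_edges=[(1, 2)])
print(f"\nwith a barrier on gangway (1, 2): d(1, 2) = {barriered.distance(1, 2)} edges",
      "(was 1)")
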