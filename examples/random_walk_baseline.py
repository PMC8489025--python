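"""The pure random-walk baseline of maze performance.

A memoryless navigator (eta = 0, foresight F = 0) picks each next node
uniformly among the current node's neighbors, never reversing.  Over
protocol-constrained start-goal pairs its paths average about four times
the shortest path — a mean log10 relative trial length (RTL) near 0.6.
That value is the floor against which learning is measured: real animals
start near it and improve toward 0.2-0.3.
"""

import numpy as np

from hexnav import SimParams, build_hexmaze, generate_protocol, simulate_dataset

maze = build_hexmaze()
rng = np.random.default_rng(1)

pairs = []
for animal in range(4):  # goals counterbalanced: one in four on the inner ring
    ring = "inner" if animal % 4 == 3 else "outer"
    proto = generate_protocol(maze, "build_up", rng=rng, goal_ring=ring)
    pairs += [(start, sess.goal) for sess in proto.sessions for start in sess.starts]

trials = simulate_dataset(maze, pairs, SimParams(eta=0.0, foresight=0.0),
                          n_reps=50, rng=rng)
logs = [np.log10(t.steps / maze.distance(t.start, t.goal))
        for t in trials if t.completed]

print(f"start-goal pairs: {len(pairs)}, simulated runs: {len(logs)}")
print(f"mean log10 RTL = {np.mean(logs):.3f}   (circa 0.6: ~4x the shortest path)")
print(f"geometric-mean RTL = {10 ** np.mean(logs):.2f}")
print(f"median RTL = {np.median([10 ** v for v in logs]):.2f}")
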