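"""Goal-shuffle surrogate: the specificity control for learning effects.

A synthetic learning dataset is generated with foresight rising across
trial bins (naive first trials, near-trained late trials).  Raw RTL
distributions then differ between early and late bins — the learning
trend.  Shuffling goal labels across trials within each block and
re-scoring RTL against the surrogate goals (RTL = 10 when a trajectory
never visits its surrogate goal) destroys the goal-trajectory pairing, so
the trend must vanish if it is genuinely goal-directed.
"""

import numpy as np

from hexnav import (GroundTruthSchedule, build_hexmaze, generate_dataset,
                    gl_shuffle, group_trials, ks_two_sample, relative_trial_length)

maze = build_hexmaze()
rng = np.random.default_rng(4)

trials, _ = generate_dataset(maze, GroundTruthSchedule.build_up_like(),
                             n_animals=8, rng=rng)
groups = group_trials([t for t in trials if t.completed])

raw, shuffled = {}, {}
for b in ("t2_11", "t22_31"):
    block = [t for s in (1, 2, 3) for t in groups[("build_up", s, b)]]
    raw[b] = [relative_trial_length(t, maze).rtl for t in block]
    shuffled[b] = [m.rtl for m in gl_shuffle(block, maze, rng=rng)]

d_raw, p_raw = ks_two_sample(raw["t2_11"], raw["t22_31"])
d_sh, p_sh = ks_two_sample(shuffled["t2_11"], shuffled["t22_31"])

print(f"early bin (trials 2-11):  median RTL {np.median(raw['t2_11']):.2f}")
print(f"late bin (trials 22-31):  median RTL {np.median(raw['t22_31']):.2f}")
print(f"raw early-vs-late KS:      D = {d_raw:.3f}, p = {p_raw:.2g}  (learning trend)")
print(f"shuffled early-vs-late KS: D = {d_sh:.3f}, p = {p_sh:.2g}  (trend abolished)")
print("\np > 0.1 after shuffling shows the raw trend is specific to the true "
      "goal locations, not an artifact of trajectory statistics.")
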