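# Methods

## The maze as a graph

The HexMaze is stored as an undirected graph: 24 intersection nodes, 30
gangway edges, arranged as six regular hexagons around a central hexagonal
circuit.  The construction is geometric — seven hexagons of side 36.3 cm are
laid out in the plane, coincident vertices merged — which guarantees the
printed structural facts (24/30 counts, twelve two-way and twelve three-way
choice points, a 6-cycle inner ring of three-way nodes and an 18-cycle outer
ring, bipartiteness) rather than asserting them.  Node numbering is a
package convention (1–6 inner ring counter-clockwise from due east, 7–24
outer ring likewise, spokes joining k to 7 + 3(k−1)); the physical maze's
own numbering is not published, so any consistent labelling is admissible
but ours should not be assumed identical to it.  Gangways are physically
bidirectional, so the graph is undirected; the no-reversal constraint of
walkers is a property of the walker, not the graph.  Barriers are modelled
purely as edge removals and must leave the graph connected; construction
fails otherwise, naming the offending edges.

All analysis distances are in edges.  Planar coordinates (cm) are carried
for plotting only.

### Geodesic-node sets

The set O(s, g) of nodes lying on any shortest s→g path is enumerated
exactly: v ∈ O(s, g) iff d(s, v) + d(v, g) = d(s, g), with distances from
two breadth-first searches.  A noisy-weight variant — repeat Dijkstra on
weights 1 + Uniform(0, noise) and collect every winning path's nodes — is
kept as a validation mode because it mirrors how such sets are often
computed in practice; `noise < 1/30` guarantees perturbations can never
promote a longer path, and with 100–200 repetitions the union converges to
the exact set (checked over all 552 ordered pairs in the tests).  Defaults:
`n_reps=100`, noise ~ Uniform(0, 1e-3).

## Trial statistics

**RTL.**  Length is counted in *edges traversed* until the first goal
arrival, divided by d(start, goal).  (Counting nodes instead of edges would
shift numerator and denominator by one and a geodesic would no longer score
exactly 1.)  RTL is undefined for start = goal and for trials that never
reach the goal; both raise, except in the shuffle surrogate where an absent
goal receives the conventional penalty RTL = 10.

**DFOP.**  For each visited node, the distance to the nearest member of
O(s, g).  "Time" is graph steps (per visited node), not wall clock — the
data carry no timestamps.  Group profiles report per-step mean, SD and
count up to a horizon H (default: the 95th percentile of the group's trial
lengths).  Completed trials are padded with zeros beyond their end up to H:
the goal lies on the optimal path, so a distance-0 continuation is the
natural extension, and it lets the group mean converge to zero instead of
being dominated by the few longest trials.  Unpadded profiles are available
(`pad=False`).

**Ring occupancy** is node-weighted (fraction of visited-node entries on
the outer ring); inner and outer fractions sum to 1 because the rings
partition the nodes.

**Trial grouping.**  Within each session: trial 1 alone, then 2–11, 12–21,
22–31; trials beyond 31 are excluded everywhere.

**Goal shuffle.**  Goal labels are permuted without replacement across a
trial block and each trial re-scored against its surrogate goal using the
sub-trajectory up to that goal's first occurrence (RTL = 10 if absent).  An
assignment giving a trial its own start node (RTL = 0/0) is repaired by
swapping with a compatible position; this matters because blocks pool many
trials per animal, so a conflict-free permutation is essentially never found
by whole-permutation rejection.

**Bootstraps.**  Means and SDs of derived quantities use 50 resamples with
replacement, seeded.

## The difference-of-Gaussians parametrization

Group DFOP profiles are fitted with

    g(x) = A · (exp(−x²/2L1²) − exp(−x²/2L2²)) / Z,   L1 > L2 > 0,

where Z is the maximum of the bracketed difference over x ≥ 0, so g(0) = 0
and max g = A exactly.  The Gaussians are unit-amplitude, *not* densities:
with density normalization the difference would be negative at the origin
whenever L1 > L2, contradicting a bump that rises from zero.  Z is computed
on a grid of step 0.01 over [0, 3·L1]; the curve's analytic argmax
x\* = sqrt(2 ln(L1²/L2²)/(1/L2² − 1/L1²)) is exposed separately and used as
a cross-check in tests.

The fit is bounded least squares (`scipy.optimize.least_squares`,
tolerances 1e-8) on the parametrization (A, L2, δ) with L1 = L2 + δ, which
enforces L1 > L2 by construction; one data-driven start plus nine seeded
random restarts, best residual sum of squares wins.  Flat profiles
(max < 1e-6) return a degenerate fit with A = 0 rather than an arbitrary
optimizer artifact.  Noise-free curves from the model class are recovered
to better than 1% over A ∈ [0.5, 3], L1 ∈ [4, 15], L2 ∈ [1, 4].  Reported
descriptors: A ("amount of stray", edges), the argmax ("steps to reach the
maximum") and L1 ("steps to go back").  Fits are pooled per trial group by
default; a per-animal variant is a caller-side loop over per-animal groups.

## The generative navigator

State: current node, previous node, and an optional committed run (a stored
path being followed).  Per arrival at a node:

1. stop if it is the goal;
2. **foresight check** — draw x ~ Exponential(mean F); if d(node, goal) < x,
   append a randomly chosen geodesic to the goal and stop.  Implemented as
   a uniform draw compared with the survival function exp(−d/F), which is
   the same event.  The check runs at *every* arrival, including the start
   node and during diagonal runs (the run is simply abandoned);
3. if a committed run is in progress, follow its next node (new runs cannot
   start during a run);
4. otherwise, with probability η, commit to a **diagonal run**: a uniformly
   chosen outer-ring node at distance ≥ 3, reached along a randomly chosen
   shortest path;
5. otherwise step uniformly among neighbors excluding the previous node (at
   the start, among all neighbors).

No immediate reversal (a, b, a) ever occurs: committed runs (diagonal or
foresight) are restricted to geodesics whose first step is not the previous
node, falling back — in the rare case every geodesic reverses — to a
shortest path computed with the just-used gangway excluded.  On barriered
mazes a dead-end node (degree 1) permits the only possible move, a
turn-around; the base maze has none.  Trials are censored at `max_steps`
(default 5000; at η = 0, F = 0 censoring occurs in far less than 0.1% of
runs) and censored runs are excluded from RTL distributions, with the count
reported.

The walk consumes exactly three uniforms per step (foresight, run
initiation, move) plus extra draws only at committed-run events.  This
fixed layout makes walks driven by the same seed identical across parameter
values until a decision actually differs, which the grid fit exploits
(below).

## Strategy fitting

For each grid point (η, F) the navigator simulates `n_reps` runs per
observed trial at that trial's start and goal; the objective is the
two-sample KS distance between observed and pooled simulated RTL
distributions.  Defaults: η ∈ {0, 0.02, …, 0.20}, F ∈ {0, 0.1, …, 4.0}
(fitted foresight in practice stays below 2; the grid doubles that for
margin), `n_reps = 50` mirroring the 50-runs-per-trial augmentation scheme.
Max-DFOP and outer-ring distributions are *held out* and compared only at
the selected pair, as a validation that a model fitted on trial lengths
alone also captures spatial structure.  The KS D doubles as the effect
size; significance claims require n·m/(n+m) ≥ 50.

Two numerical choices matter:

- **Common random numbers.**  Every grid point replays the same
  pregenerated per-(trial, rep) uniforms (with a seeded overflow stream for
  walks that outrun their block).  Combined with the fixed draw layout,
  simulations at nearby parameters stay step-for-step identical until a
  decision differs, so the KS surface is smooth in the parameters instead
  of being dominated by independent Monte-Carlo noise.  Without this, the
  argmin wanders visibly along flat directions of the surface.
- **Parsimonious selection in η.**  The diagonal-run probability has only a
  weak RTL signature: its KS profile is flat to within sampling noise at
  realistic sample sizes.  Grid points whose KS distance lies within one
  observed-ECDF noise unit (1/√n_observed, the Kolmogorov scale of
  sup-norm ECDF fluctuations) of the grid minimum are treated as
  statistically tied, and ties resolve to the smallest η; F — the parameter
  of interest — is then the strict argmin within that η's row (exact F ties
  resolve to the smaller F).  Biasing F toward small values instead would
  corrupt the learning readout, which is why the parsimony applies to the
  nuisance direction only.  When the data genuinely demand η > 0, its row
  minimum separates from η = 0 by more than the noise unit and is selected.

`foresight_trajectory` applies the fit per (condition, session, bin) group,
excludes groups below the effective-sample-size floor, and bootstraps the
best pair by resampling observed trials (50 resamples); because the
simulated RTL pools are cached per grid point, a bootstrap refit costs only
KS recomputations.  Group-to-group comparisons of foresight use KS on the
bootstrap distributions of best-fit F — one defensible construction among
several, flagged as such.

## Synthetic protocols and datasets

`generate_protocol` rejection-samples (cap 10⁴ attempts per session) start
sequences satisfying the experiment's rules: start ≠ goal, d(start, goal) ≥
2 and d(consecutive starts) ≥ 2 ("at least two choice points" is read as
graph distance ≥ 2 edges), no immediate repeats, at least 60% of a
session's trials with a unique geodesic (sampling is biased toward
unique-geodesic starts so the quota is met reliably, then verified), and a
session-first start differing from the previous session's first and last.
Goals are counterbalanced one-in-four on the inner ring across animals.
Barrier updates draw 1–3 removable edges that keep the maze connected and
change the goal's geodesic-node set from at least half of that session's
starts; the set stays fixed across the update's three sessions.  Barrier
positions are not published, so these are generated, not reproduced.

`generate_dataset` drives the navigator with a known per-(condition,
session, bin) schedule of (η, F) and returns the trials alongside the
ground truth, enabling end-to-end parameter-recovery scoring.  The stock
`build_up_like` schedule emulates initial learning: η = 0 throughout and
foresight rising from 0 to 2 within and across sessions, with a partial
rollback at each session's first trial (the seesaw of real learning
curves); 0 is a naive animal and 2 the upper end of fitted values.

What the generator does *not* emulate: wall-clock dwell times, probe-trial
food omissions, motivational drift, inter-animal variability beyond the
goal counterbalancing, and any within-trial kinematics.  Passing recovery
tests therefore show the *pipeline* is consistent — statistics computed
from model-generated data return the generating parameters — not that real
mice obey the model.

## Problem sizes and determinism

Every stochastic routine takes an `rng` (seed or numpy Generator) and is
bitwise reproducible under a fixed seed.  The test suite runs the heavier
checks at these sizes, chosen to keep each quantity's sampling error well
inside its acceptance margin: the random-walk baseline on 372
protocol-constrained pairs × 50 runs; geodesic-set agreement over all 552
ordered pairs at 200 noisy repetitions; parameter recovery with datasets of
75 experimental pairs × 50 runs (the 50× augmentation convention) fitted on
the full default grid with one simulated run per observed trajectory, for
F_true ∈ {0, 0.5, 1.0, 1.5, 2.0}; the shuffle null and validation
comparisons on datasets of 4–8 animals × 3 sessions × 31 trials.

## Known limitations

- η is close to non-identified from RTL distributions outright: across the
  whole default grid range the large-sample KS separation between η = 0 and
  η = 0.2 is only D ≈ 0.006-0.014 (depending on F), so at realistic sample
  sizes the parsimonious selection effectively reports the smallest η
  consistent with the data — usually 0.  This is stated rather than hidden
  behind an arbitrary argmin; detecting η would need effective sample sizes
  of order 10^4, or fitting on statistics richer than RTL.
- The KS objective treats RTL values as exchangeable across a group's
  start–goal pairs; heterogeneous distances enter only through the
  normalization.
- The DoG normalization grid (step 0.01) limits Z accuracy for very small
  L2 (< 0.1), which the parameter bounds exclude.
- Degenerate (flat) DFOP profiles return A = 0 with scale parameters at
  their bounds; downstream code must check the `degenerate` flag rather
  than interpret those scales.
- The trajectory CSV stores a `goal` column beyond the minimal dialect
  because censored trials cannot recover their goal from the node sequence;
  files without it are accepted with goal = last node.
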