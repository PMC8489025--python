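"""Fitting the navigator's (eta, F) parameters to observed trial groups.

For every grid point (eta, F) the navigator simulates ``n_reps`` runs per
observed trial, using the observed start and goal nodes.  The fit objective
is the two-sample Kolmogorov-Smirnov distance between the observed and the
pooled simulated RTL distributions; the best pair minimizes it (selection
rule below).  Max-DFOP and outer-ring-occupancy
distributions are *held out*: they are compared only at the best pair, as a
validation that a model fitted on trial lengths alone also captures the
spatial structure of the trajectories.

The KS D statistic doubles as the effect size; significance claims require
an effective sample size n*m/(n+m) of at least 50.

The diagonal-run probability eta has only a weak signature in RTL
distributions, so its KS profile is nearly flat and a plain argmin would
pick an arbitrary grid point within the noise floor.  Selection therefore
treats grid points whose KS distance lies within one observed-ECDF
sampling-noise unit (1/sqrt(n_observed), the Kolmogorov scale below which
the statistic cannot distinguish two distributions) of the grid minimum as
ties, and resolves them toward the most parsimonious model: the smallest
such eta, with F the strict argmin within that eta's row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._util import as_generator
from .errors import FitError, ParameterError
from .maze import MazeGraph
from .metrics import relative_trial_length
from .simulate import SimParams, simulate_trial
from .trajectory import Trajectory, group_trials

#: default search grids; fitted foresight in practice stays below 2, the
#: grid extends to 4 for a 2x safety margin.
GRID_ETA = tuple(np.round(np.arange(0.0, 0.20001, 0.02), 3))
GRID_F = tuple(np.round(np.arange(0.0, 4.00001, 0.1), 2))

#: minimum effective sample size n*m/(n+m) for significance claims
MIN_EFFECTIVE_N = 50


def ks_statistic(x, y) -> float:
    """Two-sample KS D (sup-norm CDF distance) without the p-value machinery."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ParameterError("KS statistic requires two nonempty samples")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def ks_two_sample(x, y) -> tuple:
    """Two-sample KS test: (D statistic, p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("KS test requires two nonempty samples")
    res = stats.ks_2samp(x, y)
    return float(res.statistic), float(res.pvalue)


def effective_n(n: int, m: int) -> float:
    """KS effective sample size n*m/(n+m)."""
    return n * m / (n + m)


@dataclass
class StrategyFitResult:
    """KS surface over the (eta, F) grid with the best pair and validation."""

    grid_eta: tuple
    grid_F: tuple
    ks_rtl: np.ndarray           # shape (len(grid_eta), len(grid_F))
    best_eta: float
    best_F: float
    p_value: float               # KS p at the best pair (RTL)
    effect_size: float           # KS D at the best pair (RTL)
    n_eff: float
    d_maxdfop: float = float("nan")
    p_maxdfop: float = float("nan")
    d_ring: float = float("nan")
    p_ring: float = float("nan")
    n_censored: int = 0
    sim_rtls: Optional[dict] = field(default=None, repr=False)

    @property
    def best(self) -> tuple:
        return (self.best_eta, self.best_F)


def _select_best(ks: np.ndarray, grid_eta, grid_F, n_obs: int) -> tuple:
    """Pick (i, j) on the KS surface: smallest eta whose row minimum ties the
    global minimum within one observed-ECDF sampling-noise unit (1/sqrt(n),
    the Kolmogorov scale of sup|ECDF - CDF| fluctuations), then the strict
    argmin over F in that row (first occurrence = smallest F).

    Differences in KS distance below that scale cannot be attributed to the
    parameters, so they resolve toward the more parsimonious (smaller) eta;
    F, the parameter of interest, keeps its strict row argmin.  Grids must
    be ascending.
    """
    row_min = ks.min(axis=1)
    tol = 1.0 / math.sqrt(n_obs)
    i = int(np.flatnonzero(row_min <= row_min.min() + tol)[0])
    j = int(np.argmin(ks[i]))
    return i, j


def _observed_rtls(observed: Sequence[Trajectory], maze: MazeGraph) -> np.ndarray:
    vals = []
    for t in observed:
        if not t.completed:
            raise ParameterError("strategy fitting requires completed trials only")
        vals.append(t.steps / maze.distance(t.start, t.goal))
    return np.asarray(vals, dtype=float)


def _simulate_rtls(maze, specs, params, table, overflow_seeds):
    """Per-spec arrays of simulated RTLs (censored runs dropped) + censor count.

    ``table`` holds pregenerated uniforms of shape (n_specs, n_reps, block)
    and ``overflow_seeds`` the per-(trial, rep) seeds for walks that outrun
    their block.  Replaying the *same* table at every grid point couples the
    simulations across parameter values (common random numbers): thanks to
    the navigator's fixed per-step draw layout, runs at nearby (eta, F)
    stay identical until a decision actually differs, so differences in the
    KS surface reflect the parameters rather than independent Monte-Carlo
    noise.
    """
    from ._util import ReplayStream
    from .simulate import _walk

    eta, f, max_steps = params.eta, params.foresight, params.max_steps
    per_spec, censored = [], 0
    for k, (start, goal) in enumerate(specs):
        d = maze.distance(start, goal)
        vals = []
        for r in range(table.shape[1]):
            stream = ReplayStream(table[k, r], int(overflow_seeds[k, r]))
            nodes, completed = _walk(maze, start, goal, eta, f, max_steps, stream)
            if completed:
                vals.append((len(nodes) - 1) / d)
            else:
                censored += 1
        per_spec.append(np.asarray(vals, dtype=float))
    return per_spec, censored


def fit_strategy(observed: Sequence[Trajectory], maze: MazeGraph,
                 grid_eta=GRID_ETA, grid_F=GRID_F, n_reps: int = 50,
                 rng=None, max_steps: int = 5000,
                 keep_rtls: bool = False, validate: bool = True) -> StrategyFitResult:
    """Grid-search (eta, F) by minimizing KS distance on RTL distributions.

    Parameters
    ----------
    observed : completed trajectories sharing a trial group
    grid_eta, grid_F : parameter grids to scan
    n_reps : simulated runs per observed trial per grid point
    keep_rtls : retain per-grid-point, per-trial simulated RTL arrays
        (needed for cheap bootstrap refits)
    validate : compare held-out max-DFOP and ring-occupancy distributions
        at the best pair
    """
    if not observed:
        raise ParameterError("fit_strategy requires observed trials")
    grid_eta, grid_F = tuple(grid_eta), tuple(grid_F)
    if not grid_eta or not grid_F:
        raise ParameterError("parameter grids must be nonempty")
    rng = as_generator(rng)
    obs_rtl = _observed_rtls(observed, maze)
    specs = [(t.start, t.goal) for t in observed]
    # pregenerated uniforms per (trial, rep), replayed at every grid point
    # (common random numbers); overflow seeds cover unusually long walks
    table = rng.random((len(specs), n_reps, 384))
    overflow = rng.integers(0, 2**31, size=(len(specs), n_reps))

    ks = np.full((len(grid_eta), len(grid_F)), np.nan)
    pools = {}
    sim_store = {} if keep_rtls else None
    total_censored = 0
    for i, eta in enumerate(grid_eta):
        for j, f in enumerate(grid_F):
            params = SimParams(eta=eta, foresight=f, max_steps=max_steps)
            per_spec, cens = _simulate_rtls(maze, specs, params, table, overflow)
            total_censored += cens
            pooled = np.concatenate(per_spec) if per_spec else np.array([])
            ks[i, j] = 1.0 if pooled.size == 0 else ks_statistic(obs_rtl, pooled)
            pools[(i, j)] = pooled
            if sim_store is not None:
                sim_store[(i, j)] = per_spec
    bi, bj = _select_best(ks, grid_eta, grid_F, obs_rtl.size)
    best_eta, best_f = grid_eta[bi], grid_F[bj]
    best_pool = pools[(bi, bj)]
    if best_pool.size == 0:
        raise FitError("every grid point produced censoring-dominated simulations")
    d_best, p_best = ks_two_sample(obs_rtl, best_pool)
    n_eff = effective_n(obs_rtl.size, best_pool.size)

    res = StrategyFitResult(
        grid_eta=grid_eta, grid_F=grid_F, ks_rtl=ks,
        best_eta=float(best_eta), best_F=float(best_f),
        p_value=p_best, effect_size=d_best, n_eff=n_eff,
        n_censored=total_censored, sim_rtls=sim_store,
    )
    if validate:
        _validate_at_best(res, observed, maze, n_reps, max_steps, rng)
    return res


def _validate_at_best(res: StrategyFitResult, observed, maze, n_reps, max_steps, rng):
    """Held-out comparison of max-DFOP and outer-ring fraction at the best pair."""
    params = SimParams(eta=res.best_eta, foresight=res.best_F, max_steps=max_steps)
    obs_m = [relative_trial_length(t, maze) for t in observed]
    sim_m = []
    for t in observed:
        for _ in range(n_reps):
            s = simulate_trial(maze, t.start, t.goal, params, rng=rng)
            if s.completed:
                sim_m.append(relative_trial_length(s, maze))
    if not sim_m:
        return
    res.d_maxdfop, res.p_maxdfop = ks_two_sample(
        [m.max_dfop for m in obs_m], [m.max_dfop for m in sim_m])
    res.d_ring, res.p_ring = ks_two_sample(
        [m.outer_fraction for m in obs_m], [m.outer_fraction for m in sim_m])


def bootstrap_best_fit(res: StrategyFitResult, observed, maze,
                       n_boot: int = 50, rng=None) -> tuple:
    """Bootstrap spread of the best-fit pair by resampling observed trials.

    Requires a result built with ``keep_rtls=True``: each resample reuses
    the already-simulated RTL pools of the resampled trials, so refits cost
    only KS recomputations.  Returns (boot_eta, boot_F) arrays.
    """
    if res.sim_rtls is None:
        raise ParameterError("bootstrap_best_fit needs fit_strategy(..., keep_rtls=True)")
    rng = as_generator(rng)
    obs_rtl = _observed_rtls(observed, maze)
    n = obs_rtl.size
    ne, nf = len(res.grid_eta), len(res.grid_F)
    boot_eta, boot_f = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        obs_b = np.sort(obs_rtl[idx])
        ks = np.ones((ne, nf))
        for i in range(ne):
            for j in range(nf):
                pools = res.sim_rtls[(i, j)]
                sim_b = np.concatenate([pools[k] for k in idx])
                if sim_b.size:
                    ks[i, j] = ks_statistic(obs_b, sim_b)
        bi, bj = _select_best(ks, res.grid_eta, res.grid_F, n)
        boot_eta.append(res.grid_eta[bi])
        boot_f.append(res.grid_F[bj])
    return np.asarray(boot_eta), np.asarray(boot_f)


@dataclass
class GroupStrategyFit:
    """Per-trial-group fit with its bootstrap spread of the best pair."""

    condition: str
    session: int
    bin: str
    fit: StrategyFitResult
    boot_eta: np.ndarray
    boot_F: np.ndarray


def foresight_trajectory(trials: Sequence[Trajectory], maze: MazeGraph,
                         grid_eta=GRID_ETA, grid_F=GRID_F, n_reps: int = 50,
                         n_boot: int = 50, rng=None,
                         min_n_eff: float = MIN_EFFECTIVE_N) -> dict:
    """Best-fit (eta, F) per (condition, session, bin) group, with bootstrap.

    Groups whose effective sample size would fall below ``min_n_eff`` are
    excluded with a warning.  The per-group bootstrap F distributions can be
    compared between groups with :func:`ks_two_sample` to test whether
    foresight changed over learning.
    """
    rng = as_generator(rng)
    out = {}
    for (cond, sess, b), group in group_trials(trials).items():
        n = len(group)
        n_eff = effective_n(n, n * n_reps)
        if n_eff < min_n_eff:
            warnings.warn(f"group {(cond, sess, b)}: effective n {n_eff:.1f} < "
                          f"{min_n_eff}, excluded", stacklevel=2)
            continue
        fit = fit_strategy(group, maze, grid_eta=grid_eta, grid_F=grid_F,
                           n_reps=n_reps, rng=rng, keep_rtls=True)
        boot_eta, boot_f = bootstrap_best_fit(fit, group, maze, n_boot=n_boot, rng=rng)
        fit.sim_rtls = None  # free the grid-sized cache once bootstrapped
        out[(cond, sess, b)] = GroupStrategyFit(
            condition=cond, session=sess, bin=b, fit=fit,
            boot_eta=boot_eta, boot_F=boot_f)
    return out
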