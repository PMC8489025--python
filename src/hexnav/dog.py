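"""Difference-of-Gaussians parametrization of DFOP profiles.

Group-averaged DFOP profiles have a stereotyped bump shape: zero at the
start (the start node lies on the optimal path), a rise as the trajectory
strays, and a decay back to zero as it converges on the goal.  The bump is
parametrized as a normalized difference of Gaussians

    g(x) = A * (N(0, L1) - N(0, L2)) / Z,     N(0, L) = exp(-x^2 / (2 L^2))

with L1 > L2 > 0 and Z the maximum of the bracketed difference over x >= 0,
so that g(0) = 0 and max g = A exactly.  ``A`` is the peak height (edges),
``L1`` the descending length scale and ``L2`` the ascending one (steps).

The Gaussians are unit-amplitude, not probability densities: with density
normalisation the difference would be negative at the origin whenever
L1 > L2, contradicting the observed bump rising from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._util import as_generator
from .errors import FitError, ParameterError
from .metrics import DFOPProfile

#: resolution of the numerical grid used to normalise the curve
_Z_GRID_STEP = 0.01


@dataclass(frozen=True)
class DoGFit:
    """Fitted difference-of-Gaussians parameters for one DFOP profile."""

    A: float
    L1: float
    L2: float
    Z: float
    peak_step: float
    rss: float
    degenerate: bool = False


def _check_params(A: float, L1: float, L2: float):
    if A < 0:
        raise ParameterError(f"A must be >= 0, got {A}")
    if not (L1 > L2 > 0):
        raise ParameterError(
            f"need L1 > L2 > 0 (descending slower than ascending), got L1={L1}, L2={L2}")


def _normalization(L1: float, L2: float) -> float:
    """Max over x >= 0 of exp(-x^2/2L1^2) - exp(-x^2/2L2^2), on a fine grid."""
    x = np.arange(0.0, 3.0 * L1 + _Z_GRID_STEP, _Z_GRID_STEP)
    diff = np.exp(-(x ** 2) / (2 * L1 ** 2)) - np.exp(-(x ** 2) / (2 * L2 ** 2))
    return float(diff.max())


def dog_peak_location(L1: float, L2: float) -> float:
    """Analytic argmax of the unnormalized difference of Gaussians.

    Setting the derivative to zero gives
    ``x* = sqrt(2 ln(L1^2/L2^2) / (1/L2^2 - 1/L1^2))``.
    """
    if not (L1 > L2 > 0):
        raise ParameterError(f"need L1 > L2 > 0, got L1={L1}, L2={L2}")
    return math.sqrt(2.0 * math.log(L1 ** 2 / L2 ** 2) / (1.0 / L2 ** 2 - 1.0 / L1 ** 2))


def dog_curve(x, A: float, L1: float, L2: float) -> np.ndarray:
    """Evaluate the normalized difference-of-Gaussians curve at ``x``."""
    _check_params(A, L1, L2)
    x = np.asarray(x, dtype=float)
    z = _normalization(L1, L2)
    return A * (np.exp(-(x ** 2) / (2 * L1 ** 2)) - np.exp(-(x ** 2) / (2 * L2 ** 2))) / z


# -- fitting -----------------------------------------------------------------

# (A, L2, delta) box used by the optimizer; L1 = L2 + delta keeps L1 > L2.
_LOWER = np.array([0.0, 0.05, 1e-3])
_UPPER = np.array([50.0, 60.0, 200.0])
_A_EPS = 1e-6  # peak height below which a profile counts as flat


def _fit_xy(x: np.ndarray, y: np.ndarray, n_starts: int, rng) -> DoGFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise ParameterError("DoG fit requires a profile with at least 5 valid steps")
    ymax = float(y.max(initial=0.0))
    if ymax <= _A_EPS:
        return DoGFit(A=0.0, L1=float(_UPPER[1]), L2=float(_LOWER[1]), Z=1.0,
                      peak_step=0.0, rss=float(np.sum(y ** 2)), degenerate=True)

    def resid(p):
        a, l2, delta = p
        l1 = l2 + delta
        z = _normalization(l1, l2)
        return a * (np.exp(-(x ** 2) / (2 * l1 ** 2))
                    - np.exp(-(x ** 2) / (2 * l2 ** 2))) / z - y

    # one data-driven start plus seeded random restarts
    xpk = max(float(x[int(np.argmax(y))]), 1.0)
    starts = [np.array([ymax, max(0.3 * xpk, 0.2), max(1.5 * xpk, 1.0)])]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.array([
            ymax * rng.uniform(0.5, 1.5),
            rng.uniform(0.3, 8.0),
            rng.uniform(0.5, 25.0),
        ]))
    best = None
    for p0 in starts:
        p0 = np.clip(p0, _LOWER + 1e-9, _UPPER - 1e-9)
        try:
            sol = least_squares(resid, p0, bounds=(_LOWER, _UPPER),
                                xtol=1e-8, ftol=1e-8, gtol=1e-8)
        except Exception:
            continue
        if sol.success or sol.status > 0:
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        raise FitError("difference-of-Gaussians fit failed from every start")
    rss, (a, l2, delta) = best
    l1 = l2 + delta
    return DoGFit(A=float(a), L1=float(l1), L2=float(l2),
                  Z=_normalization(l1, l2),
                  peak_step=dog_peak_location(l1, l2),
                  rss=rss)


def fit_dog(profile: DFOPProfile, n_starts: int = 10, rng=None) -> DoGFit:
    """Least-squares fit of the normalized DoG curve to a DFOP profile.

    Bounded least squares with one data-driven start and seeded random
    restarts; the best residual sum of squares wins.  Flat (all-zero)
    profiles return a degenerate fit with ``A = 0``.
    """
    rng = as_generator(rng)
    return _fit_xy(profile.step, profile.mean, n_starts, rng)


def fit_dog_bootstrap(trials, maze, n_boot: int = 50, n_starts: int = 10,
                      rng=None, horizon=None, pad: bool = True) -> list:
    """Refit the DoG curve on bootstrap resamples of the trial set.

    Returns a list of :class:`DoGFit`, one per resample; summarising their
    parameters gives bootstrap means and SDs of (A, L1, L2).
    """
    from .metrics import dfop_profile  # local import to avoid cycle at import time

    if not trials:
        raise ParameterError("bootstrap DoG fit requires a nonempty trial set")
    rng = as_generator(rng)
    fits = []
    trials = list(trials)
    for _ in range(n_boot):
        sample = [trials[i] for i in rng.integers(0, len(trials), size=len(trials))]
        prof = dfop_profile(sample, maze, horizon=horizon, pad=pad)
        fits.append(_fit_xy(prof.step, prof.mean, n_starts, rng))
    return fits
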