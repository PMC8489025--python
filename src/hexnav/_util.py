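"""Small internal helpers shared across modules."""

from __future__ import annotations

import numpy as np


def as_generator(rng) -> np.random.Generator:
    """Coerce ``rng`` (None, int seed, or Generator) to a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


class UniformStream:
    """Buffered stream of U(0,1) draws from a numpy Generator.

    Scalar draws from a Generator carry noticeable per-call overhead; the
    navigation simulator consumes one or two uniforms per step, so it pulls
    them from a refillable block instead.
    """

    __slots__ = ("_rng", "_buf", "_i", "_n")

    def __init__(self, rng: np.random.Generator, block: int = 512):
        self._rng = rng
        self._n = block
        self._buf = rng.random(block)
        self._i = 0

    def next(self) -> float:
        i = self._i
        if i == self._n:
            self._buf = self._rng.random(self._n)
            i = 0
        self._i = i + 1
        return self._buf[i]


class ReplayStream:
    """Uniform stream over a pregenerated block, with a seeded overflow.

    Grid searches couple simulations across parameter values by replaying
    the same pregenerated uniforms at every grid point (common random
    numbers).  Walks long enough to exhaust their block continue from a
    generator seeded per (trial, rep), so they stay deterministic and
    identically-seeded across grid points.
    """

    __slots__ = ("_buf", "_i", "_n", "_seed", "_rng")

    def __init__(self, block, seed: int):
        self._buf = block
        self._i = 0
        self._n = block.shape[0]
        self._seed = seed
        self._rng = None

    def next(self) -> float:
        i = self._i
        if i == self._n:
            if self._rng is None:
                self._rng = np.random.default_rng(self._seed)
            self._buf = self._rng.random(512)
            self._n = 512
            i = 0
        self._i = i + 1
        return self._buf[i]
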