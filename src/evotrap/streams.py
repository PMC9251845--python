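"""Reproducible random-number streams for the simulator.

The event loop draws large numbers of scalar exponential/uniform variates,
for which the stdlib Mersenne-Twister generator is markedly faster than a
:class:`numpy.random.Generator` call; vectorised draws (Poisson offspring
counts, batches of maturation times) go through numpy.  :class:`SimRng`
bundles both behind one object, seeded from a single
:class:`numpy.random.SeedSequence` so that child streams — one per replicate,
one per grid cell — can be spawned deterministically from a master seed.
"""

from __future__ import annotations

import random

import numpy as np

__all__ = ["SimRng"]


class SimRng:
    """A pair of coupled generators derived from one seed sequence.

    Parameters
    ----------
    seed
        An integer seed or an existing :class:`numpy.random.SeedSequence`.
    """

    __slots__ = ("seed_sequence", "py", "np")

    def __init__(self, seed: int | np.random.SeedSequence):
        if isinstance(seed, np.random.SeedSequence):
            ss = seed
        else:
            ss = np.random.SeedSequence(int(seed))
        self.seed_sequence = ss
        py_ss, np_ss = ss.spawn(2)
        # 128 bits of entropy for the Mersenne Twister state
        self.py = random.Random(int.from_bytes(py_ss.generate_state(4, np.uint32).tobytes(), "little"))
        self.np = np.random.default_rng(np_ss)

    def spawn(self, n: int) -> list["SimRng"]:
        """Derive ``n`` independent child streams (deterministic given the seed)."""
        return [SimRng(child) for child in self.seed_sequence.spawn(n)]

    # -- scalar draws (hot path) --------------------------------------------

    def random(self) -> float:
        """Uniform variate on [0, 1)."""
        return self.py.random()

    def exponential(self, mean: float) -> float:
        """Exponential variate with the given mean."""
        return self.py.expovariate(1.0 / mean)

    def normal(self) -> float:
        """Standard normal variate."""
        return self.py.gauss(0.0, 1.0)

    def randrange(self, n: int) -> int:
        """Uniform integer on {0, ..., n-1}."""
        return self.py.randrange(n)

    # -- vectorised draws ----------------------------------------------------

    def poisson(self, lam: float, size: int) -> np.ndarray:
        """``size`` independent Poisson counts with mean ``lam``."""
        return self.np.poisson(lam, size)

    def exponential_array(self, mean: float, size: int) -> np.ndarray:
        """``size`` independent exponential variates with the given mean."""
        return self.np.exponential(mean, size)
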