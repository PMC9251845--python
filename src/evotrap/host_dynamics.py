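"""Host regeneration and per-host developmental clocks.

Host generations are discrete: the survivors of one generation reproduce,
scatter their offspring uniformly over the patches of their species, and die.
The offspring count per patch is Poisson with the stochastic-Ricker mean

    lambda_i = (1/n_i) * r_i * H_i * exp(-H_i / K_i)

where ``H_i`` is the adult count, so the parasitoid-free equilibrium density
is ``K_i * ln(r_i)``.  Each offspring is vulnerable to parasitism during a
sensitive developmental period of exponentially distributed length (mean
``tau_dH_i``); a host whose sensitive period ends before any qualifying
parasitoid egg completes development survives to adulthood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ParameterSet, equilibrium_density
from .streams import SimRng

__all__ = [
    "UNRESOLVED", "SURVIVED", "KILLED_REPRODUCTIVE", "KILLED_NONREPRODUCTIVE",
    "FATE_NAMES", "PatchLayout", "HostIndividual",
    "spawn_offspring", "sample_maturation_times", "initialize_hosts",
]

# Host fates, encoded as ints for the event loop.
UNRESOLVED = 0
SURVIVED = 1
KILLED_REPRODUCTIVE = 2
KILLED_NONREPRODUCTIVE = 3
FATE_NAMES = {UNRESOLVED: "unresolved", SURVIVED: "survived",
              KILLED_REPRODUCTIVE: "killed_reproductive",
              KILLED_NONREPRODUCTIVE: "killed_nonreproductive"}


@dataclass(frozen=True)
class PatchLayout:
    """Fixed patch arrangement: patches 0..n1-1 hold species 1, the rest species 2."""

    n1: int
    n2: int

    @property
    def total(self) -> int:
        return self.n1 + self.n2

    def species_of(self, patch: int) -> int:
        if not 0 <= patch < self.total:
            raise IndexError(f"patch {patch} out of range for {self.total} patches")
        return 1 if patch < self.n1 else 2


class HostIndividual:
    """One developing host: its clock, attached eggs, and eventual fate.

    ``maturation_time`` marks the end of the sensitive period, measured from
    the start of the generation.  The host is *vulnerable* (parasitizable)
    while its fate is unresolved; the fate resolves exactly once, either to
    ``SURVIVED`` at maturation or to a kill when the first qualifying egg
    completes development (see :mod:`evotrap.outcomes`).

    The trailing attributes are event-engine bookkeeping: the host's slot in
    its patch's encounterable pool, the earliest qualifying egg completion
    with its parent genotype/compatibility, and a version stamp for lazy
    invalidation of scheduled resolution events.
    """

    __slots__ = ("species", "patch", "maturation_time", "alive", "fate", "eggs",
                 "pool_index", "best_completion", "best_parent", "best_compatible",
                 "version")

    def __init__(self, species: int, patch: int, maturation_time: float):
        self.species = species
        self.patch = patch
        self.maturation_time = maturation_time
        self.alive = True
        self.fate = UNRESOLVED
        self.eggs: list = []
        self.pool_index = -1
        self.best_completion = float("inf")
        self.best_parent = None
        self.best_compatible = False
        self.version = 0

    @property
    def vulnerable(self) -> bool:
        """True while the host can still be parasitized (fate undecided)."""
        return self.fate == UNRESOLVED

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"HostIndividual(species={self.species}, patch={self.patch}, "
                f"maturation={self.maturation_time:.3f}, fate={FATE_NAMES[self.fate]})")


def spawn_offspring(H_prev: int, p: ParameterSet, species: int, rng: SimRng) -> np.ndarray:
    """Per-patch Poisson offspring counts for one host species.

    ``H_prev`` is the number of adults (survivors of the previous
    generation); each of the species' patches receives an independent
    Poisson(lambda) count with the Ricker mean above.  Extinction is
    absorbing: ``H_prev = 0`` yields all-zero counts.
    """
    if species == 1:
        n, r, K = p.n1, p.r1, p.K1
    elif species == 2:
        n, r, K = p.n2, p.r2, p.K2
    else:
        raise ValueError(f"unknown host species {species}")
    if H_prev < 0:
        raise ValueError(f"adult count must be non-negative, got {H_prev}")
    if H_prev == 0:
        return np.zeros(n, dtype=np.int64)
    lam = r * H_prev * np.exp(-H_prev / K) / n
    return rng.poisson(lam, n)


def sample_maturation_times(counts: np.ndarray, tau_dH: float, rng: SimRng,
                            species: int = 1, first_patch: int = 0) -> list[HostIndividual]:
    """Create the cohort of :class:`HostIndividual` for one species.

    One individual per offspring in ``counts`` (indexed by patch, with global
    patch ids starting at ``first_patch``); each gets an independent
    exponential sensitive-period length with mean ``tau_dH``.
    """
    if not tau_dH > 0:
        raise ValueError(f"tau_dH must be positive, got {tau_dH}")
    total = int(np.sum(counts))
    if total == 0:
        return []
    times = rng.exponential_array(tau_dH, total)
    hosts: list[HostIndividual] = []
    k = 0
    for patch_offset, c in enumerate(counts):
        pid = first_patch + patch_offset
        for _ in range(int(c)):
            hosts.append(HostIndividual(species, pid, float(times[k])))
            k += 1
    return hosts


def initialize_hosts(p: ParameterSet, rng: SimRng) -> tuple[tuple[int, int],
                                                            list[HostIndividual],
                                                            list[HostIndividual]]:
    """First-generation cohorts from parasitoid-free equilibrium adult counts.

    Adults are initialised at ``round(K_i * ln r_i)`` per species; their
    offspring cohorts are then spawned through the regular Ricker-Poisson and
    maturation sampling.  Returns ``((adults1, adults2), cohort1, cohort2)``.
    """
    adults1 = round(equilibrium_density(p.K1, p.r1))
    adults2 = round(equilibrium_density(p.K2, p.r2))
    c1 = spawn_offspring(adults1, p, 1, rng)
    c2 = spawn_offspring(adults2, p, 2, rng)
    hosts1 = sample_maturation_times(c1, p.tau_dH1, rng, species=1, first_patch=0)
    hosts2 = sample_maturation_times(c2, p.tau_dH2, rng, species=2, first_patch=p.n1)
    return (adults1, adults2), hosts1, hosts2
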