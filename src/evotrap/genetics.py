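"""Heritable parasitoid traits and their mutation kernels.

Each parasitoid carries two clonally inherited haploid loci: a continuous
host-preference trait ``q`` on [-1, +1] (q > 0 biases patch acceptance toward
host species 1, q < 0 toward species 2, q = 0 is random host search) and a
categorical parasitization strategy ``S`` in {1, 2, 3} (specialist on host 1,
specialist on host 2, generalist).  Mutation happens per reproductive event:
q jumps by a standard-normal increment clamped to the trait range; S moves
along the transition graph specialist -> generalist -> either specialist, so
a one-step specialist-to-specialist switch is impossible.
"""

from __future__ import annotations

from typing import NamedTuple

from .config import ParameterSet
from .streams import SimRng

__all__ = [
    "Genotype",
    "STRATEGIES",
    "strategy_transition_matrix",
    "is_compatible",
    "development_mean",
    "mutate_preference",
    "mutate_strategy",
    "make_offspring_genotype",
]

STRATEGIES = (1, 2, 3)


class Genotype(NamedTuple):
    """Heritable pair (host preference q, parasitization strategy S)."""

    q: float
    S: int

    def validate(self) -> "Genotype":
        if not -1.0 <= self.q <= 1.0:
            raise ValueError(f"host preference q must lie in [-1, 1], got {self.q}")
        if self.S not in STRATEGIES:
            raise ValueError(f"parasitization strategy S must be 1, 2 or 3, got {self.S}")
        return self


def is_compatible(S: int, species: int) -> bool:
    """Physiological compatibility of a strategy with a host species.

    Specialists (S=1, S=2) are compatible only with their own host species;
    generalists (S=3) with both.  Compatibility decides whether an egg can
    yield a viable offspring; what an *incompatible* attack does to the host
    depends on the scenario (see :mod:`evotrap.outcomes`).
    """
    if S not in STRATEGIES:
        raise ValueError(f"unknown strategy S={S}")
    if species not in (1, 2):
        raise ValueError(f"unknown host species {species}")
    return S == 3 or S == species


def development_mean(S_parent: int, p: ParameterSet) -> float:
    """Mean offspring development time for a mother with strategy ``S_parent``.

    Development rate depends only on the mother's strategy — never on the
    host species or on compatibility: generalist offspring develop slowly in
    every host, and an incompatible specialist egg (scenario 2) races at the
    fast specialist rate even though it can never emerge.
    """
    if S_parent == 1:
        return p.tau_dP1
    if S_parent == 2:
        return p.tau_dP2
    if S_parent == 3:
        return p.tau_dP3
    raise ValueError(f"unknown strategy S={S_parent}")


def mutate_preference(q_parent: float, mu_q: float, rng: SimRng) -> float:
    """Offspring q: with probability ``mu_q`` add a standard-normal increment.

    The mutated value is clamped to the trait range [-1, +1]; otherwise the
    parental value is inherited unchanged.
    """
    if mu_q > 0.0 and rng.random() < mu_q:
        q = q_parent + rng.normal()
        return -1.0 if q < -1.0 else (1.0 if q > 1.0 else q)
    return q_parent


def mutate_strategy(S_parent: int, mu_S: float, rng: SimRng) -> int:
    """Offspring S: with probability ``mu_S`` move along the transition graph.

    Conditional on a mutation: 1 -> 3 and 2 -> 3 with certainty; 3 -> 1 or
    3 -> 2 each with probability 1/2.  A specialist can therefore reach the
    other specialist tactic only through a generalist intermediate.
    """
    if mu_S > 0.0 and rng.random() < mu_S:
        if S_parent == 3:
            return 1 if rng.random() < 0.5 else 2
        return 3
    return S_parent


def make_offspring_genotype(parent: Genotype, p: ParameterSet, rng: SimRng) -> Genotype:
    """Clonal offspring genotype with independent per-locus mutation."""
    return Genotype(mutate_preference(parent.q, p.mu_q, rng),
                    mutate_strategy(parent.S, p.mu_S, rng))


def strategy_transition_matrix(mu_S: float = 1.0) -> "list[list[float]]":
    """Row-stochastic S-mutation matrix (rows/cols ordered 1, 2, 3).

    With ``mu_S = 1`` this is the kernel conditional on a mutation occurring;
    smaller values mix in the identity.  Exposed for analysis: its stationary
    distribution under forced mutation is (1/4, 1/4, 1/2).
    """
    stay = 1.0 - mu_S
    return [
        [stay, 0.0, mu_S],
        [0.0, stay, mu_S],
        [mu_S / 2.0, mu_S / 2.0, stay],
    ]
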