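"""Egg creation, the development-versus-maturation race, and host fate.

An egg's viability is a race between two exponential clocks: the mother's
offspring development time (mean ``tau_dP`` set by *her* strategy S, not by
the host) and the host's remaining sensitive period (memoryless, so again
exponential with mean ``tau_dH``).  A host dies if and only if some
*qualifying* egg completes development before the host matures; among
multiple eggs (superparasitism) the earliest qualifying completion is
decisive and all other eggs are inviable (solitary parasitoid).

Which eggs qualify to decide the fate depends on the scenario:

* scenario 1 — an incompatible egg is inert ("no interaction"); only
  compatible eggs can kill, and every kill yields one parasitoid offspring.
* scenario 2 — an incompatible egg develops far enough to kill the host but
  yields no offspring (non-reproductive host mortality), so every egg
  qualifies and a kill is reproductive only if the deciding egg is
  compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ParameterSet
from .genetics import Genotype, development_mean, is_compatible, make_offspring_genotype
from .foraging import ParasitoidState
from .host_dynamics import (HostIndividual, KILLED_NONREPRODUCTIVE,
                            KILLED_REPRODUCTIVE, SURVIVED, UNRESOLVED)
from .streams import SimRng

__all__ = ["Egg", "KillTally", "lay_egg", "resolve_host_fate",
           "single_attack_success_probability"]


class Egg:
    """One parasitoid egg attached to a host.

    ``compatible`` and ``qualifies`` are fixed at laying from the *mother's*
    strategy (maternal physiology) and the active scenario; the clamped race
    is then decided purely on ``completion_time``.
    """

    __slots__ = ("parent_genotype", "lay_time", "completion_time",
                 "compatible", "qualifies")

    def __init__(self, parent_genotype: Genotype, lay_time: float,
                 completion_time: float, compatible: bool, qualifies: bool):
        self.parent_genotype = parent_genotype
        self.lay_time = lay_time
        self.completion_time = completion_time
        self.compatible = compatible
        self.qualifies = qualifies


@dataclass
class KillTally:
    """Per-species bookkeeping of one generation's interaction outcomes.

    Lists are indexed by species - 1.  Reproductive kills always equal
    parasitoids emerged (solitary: one offspring per compatible deciding
    egg).
    """

    reproductive_kills: list[int] = field(default_factory=lambda: [0, 0])
    nonreproductive_kills: list[int] = field(default_factory=lambda: [0, 0])
    survived: list[int] = field(default_factory=lambda: [0, 0])
    eggs_laid: list[int] = field(default_factory=lambda: [0, 0])
    emerged: list[int] = field(default_factory=lambda: [0, 0])

    def killed(self, species: int) -> int:
        i = species - 1
        return self.reproductive_kills[i] + self.nonreproductive_kills[i]


def lay_egg(mother: ParasitoidState, host: HostIndividual, t: float,
            p: ParameterSet, rng: SimRng) -> Egg:
    """Attach a new egg to a vulnerable host and charge the mother one unit.

    The mother pays the unit of reproductive investment whether or not the
    egg is compatible — she cannot tell.  The egg's development clock starts
    now; if it qualifies and would complete earlier than every previously
    laid qualifying egg, it becomes the host's provisional decider (a
    later-laid egg can decide if it completes first).
    """
    if host.fate != UNRESOLVED:
        raise RuntimeError("attempt to oviposit in a non-vulnerable host")
    S = mother.genotype.S
    compatible = is_compatible(S, host.species)
    qualifies = True if p.scenario == 2 else compatible
    completion = t + rng.exponential(development_mean(S, p))
    egg = Egg(mother.genotype, t, completion, compatible, qualifies)
    host.eggs.append(egg)
    mother.visit_investment += 1
    if qualifies and completion < host.best_completion:
        host.best_completion = completion
        host.best_parent = mother.genotype
        host.best_compatible = compatible
    return egg


def resolve_host_fate(host: HostIndividual, p: ParameterSet, rng: SimRng,
                      tally: KillTally | None = None) -> Genotype | None:
    """Decide a host's fate once; return the emerging offspring genotype, if any.

    Let T* be the earliest completion time over qualifying eggs (infinity if
    none).  If T* precedes maturation the host dies at T*: a compatible
    decider makes the kill reproductive and emits exactly one offspring
    (clonally inherited from the decider's parent, with mutation applied at
    emergence); an incompatible decider kills without offspring.  Otherwise
    the host survives and all its eggs are inviable.
    """
    if host.fate != UNRESOLVED:
        raise RuntimeError("host fate already resolved")
    i = host.species - 1
    if host.best_completion < host.maturation_time:
        host.alive = False
        if host.best_compatible:
            host.fate = KILLED_REPRODUCTIVE
            offspring = make_offspring_genotype(host.best_parent, p, rng)
            if tally is not None:
                tally.reproductive_kills[i] += 1
                tally.emerged[i] += 1
            return offspring
        host.fate = KILLED_NONREPRODUCTIVE
        if tally is not None:
            tally.nonreproductive_kills[i] += 1
        return None
    host.fate = SURVIVED
    if tally is not None:
        tally.survived[i] += 1
    return None


def single_attack_success_probability(tau_dP: float, tau_dH: float) -> float:
    """Closed-form kill probability of a lone qualifying egg.

    At any lay time the host's remaining sensitive period is again
    exponential with mean ``tau_dH`` (memorylessness), so the egg wins the
    race with probability ``tau_dH / (tau_dH + tau_dP)``.
    """
    if not (tau_dP > 0 and tau_dH > 0):
        raise ValueError("both mean development times must be positive")
    return tau_dH / (tau_dH + tau_dP)
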