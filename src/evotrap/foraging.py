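"""The within-generation behavioural cycle of one foraging parasitoid.

A female alternates between three phases: searching the environment for a
patch (exponential waiting time, mean ``tau_s``), exploiting a patch, and
recovering after leaving it (one exponential waiting time of mean ``tau_r``
per egg laid during the visit).  On finding a patch she may reject it based
on her heritable preference q — rejection costs only the search time for the
next patch.  Inside a patch, each encounterable host generates encounters as
an independent Poisson process with per-host mean interval ``tau_e``; she
leaves when she meets the same individual a second time during the visit, or
when ``tau_a`` time units pass without any encounter.  The recovery pause is
what makes the emergent per-host attack rate saturate with host density
(a Holling type-2 functional response).
"""

from __future__ import annotations

from .genetics import Genotype
from .host_dynamics import PatchLayout
from .streams import SimRng

__all__ = [
    "SEARCHING", "IN_PATCH", "RECOVERING",
    "ParasitoidState",
    "sample_search_time", "choose_patch", "rejection_probability",
    "accepted_patch_species_probability", "next_encounter",
    "leave_patch_decision", "sample_recovery_time",
]

SEARCHING = 0
IN_PATCH = 1
RECOVERING = 2


class ParasitoidState:
    """A foraging female: genotype, behavioural phase, and per-visit memory.

    ``visit_encountered`` holds the host individuals met during the current
    patch visit (cleared on every patch entry); ``visit_investment`` counts
    the eggs laid this visit and sets the length of the recovery pause.
    ``last_encounter_time`` anchors the abandonment clock — it is the patch
    entry time until the first encounter.
    """

    __slots__ = ("genotype", "phase", "patch", "visit_encountered",
                 "visit_investment", "last_encounter_time", "version")

    def __init__(self, genotype: Genotype):
        self.genotype = genotype
        self.phase = SEARCHING
        self.patch = -1
        self.visit_encountered: set = set()
        self.visit_investment = 0
        self.last_encounter_time = 0.0
        self.version = 0

    def enter_patch(self, patch: int, t: float) -> None:
        """Reset per-visit memory on patch entry."""
        self.phase = IN_PATCH
        self.patch = patch
        self.visit_encountered = set()
        self.visit_investment = 0
        self.last_encounter_time = t

    def leave_patch(self) -> None:
        self.phase = RECOVERING if self.visit_investment > 0 else SEARCHING
        self.patch = -1


def sample_search_time(tau_s: float, rng: SimRng) -> float:
    """Exponential waiting time (mean ``tau_s``) until the next patch is found.

    Memoryless, so it is simply redrawn after every rejection or departure.
    """
    if not tau_s > 0:
        raise ValueError(f"tau_s must be positive, got {tau_s}")
    return rng.exponential(tau_s)


def choose_patch(layout: PatchLayout, rng: SimRng) -> int:
    """Uniformly random patch id — search is blind to patch contents."""
    if layout.total < 1:
        raise ValueError("patch layout is empty")
    return rng.randrange(layout.total)


def rejection_probability(q: float, species: int) -> float:
    """Probability that a female with preference q rejects a located patch.

    ``max(0, -q)`` for a species-1 patch and ``max(0, +q)`` for a species-2
    patch: q = 0 accepts everything, q = +1 visits only host-1 patches,
    q = -1 only host-2 patches.
    """
    if not -1.0 <= q <= 1.0:
        raise ValueError(f"preference q must lie in [-1, 1], got {q}")
    if species == 1:
        return max(0.0, -q)
    if species == 2:
        return max(0.0, q)
    raise ValueError(f"unknown host species {species}")


def accepted_patch_species_probability(q: float, layout: PatchLayout) -> float:
    """Closed-form probability that the next *accepted* patch holds species 1.

    With acceptance probabilities a1 = 1 - max(0, -q), a2 = 1 - max(0, q) and
    uniform patch choice, the search/reject/repeat loop accepts a species-1
    patch with probability ``n1*a1 / (n1*a1 + n2*a2)``.  Serves as the
    analytic oracle for the simulated search loop.  (a1 and a2 cannot both
    vanish for q in [-1, 1].)
    """
    a1 = (1.0 - rejection_probability(q, 1)) * layout.n1
    a2 = (1.0 - rejection_probability(q, 2)) * layout.n2
    return a1 / (a1 + a2)


def next_encounter(m: int, tau_e: float, rng: SimRng) -> tuple[float, int] | None:
    """Waiting time to the next host encounter and which host it is.

    The superposition of ``m`` independent per-host Poisson processes (each
    with mean interval ``tau_e``) is exponential with mean ``tau_e / m``, and
    the encountered host is uniform among the ``m``.  Returns ``None`` when
    the patch holds no encounterable host.  Memoryless, so the engine redraws
    it after every encounter and whenever ``m`` changes.
    """
    if not tau_e > 0:
        raise ValueError(f"tau_e must be positive, got {tau_e}")
    if m < 0:
        raise ValueError(f"host count must be non-negative, got {m}")
    if m == 0:
        return None
    return rng.exponential(tau_e / m), rng.randrange(m)


def leave_patch_decision(state: ParasitoidState, host, t: float, tau_a: float) -> bool:
    """Should the female leave the patch, given this event?

    ``host`` is the encountered host individual, or ``None`` for a timeout
    check.  She leaves on the second encounter with the same individual
    during this visit (without further oviposition), or once ``tau_a`` time
    units have elapsed since her last encounter (since patch entry if none).
    """
    if host is not None and host in state.visit_encountered:
        return True
    return t - state.last_encounter_time >= tau_a


def sample_recovery_time(k: int, tau_r: float, rng: SimRng) -> float:
    """Recovery pause after a visit with ``k`` units of reproductive investment.

    A sum of ``k`` independent exponential waiting times of mean ``tau_r``
    (Gamma with shape ``k`` and scale ``tau_r``); zero when nothing was laid.
    """
    if k < 0:
        raise ValueError(f"investment must be non-negative, got {k}")
    if not tau_r > 0:
        raise ValueError(f"tau_r must be positive, got {tau_r}")
    total = 0.0
    for _ in range(k):
        total += rng.exponential(tau_r)
    return total
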