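"""Continuous-time event engine, generation turnover, replicates and grids.

Within a generation the simulator is a stochastic event-driven system in the
Gillespie tradition: every waiting time is exponential, so the next event of
each kind can be drawn directly and merged through a single priority queue
ordered by ``(time, sequence_number)``.  Each foraging parasitoid owns
exactly one pending event (find patch / encounter / leave) and every
unresolved host owns exactly one pending resolution event scheduled at
``min(maturation, earliest qualifying egg completion)``; events invalidated
by state changes (a host killed in an occupied patch, an earlier decider
egg) are superseded through per-actor version stamps and lazily skipped when
popped, which keeps every draw memoryless and the whole trajectory
reproducible from the seed.

Generations are discrete and non-overlapping: the loop runs until no
vulnerable host remains anywhere, emerged offspring replace the parental
parasitoid generation, surviving hosts seed the next Ricker spawn, and the
clock resets.
"""

from __future__ import annotations

import heapq

import numpy as np

from .config import ExperimentDesign, ParameterSet, validate_parameters
from .foraging import ParasitoidState
from .genetics import Genotype
from .host_dynamics import (HostIndividual, PatchLayout, SURVIVED, UNRESOLVED,
                            initialize_hosts, sample_maturation_times,
                            spawn_offspring)
from .outcomes import KillTally, lay_egg, resolve_host_fate
from .reporting import (GenerationRecord, GridSummary, ReplicateResult,
                        record_generation, summarize_replicates)
from .streams import SimRng

__all__ = ["EV_PATCH_FOUND", "EV_ENCOUNTER", "EV_LEAVE", "EV_RESOLVE",
           "GenerationState", "run_generation", "run_replicate", "run_grid"]

# Event kinds (payload is the actor object itself).
EV_PATCH_FOUND = 0
EV_ENCOUNTER = 1
EV_LEAVE = 2
EV_RESOLVE = 3


class GenerationState:
    """Mutable state of one generation's event simulation.

    Holds the host cohorts, the adult parasitoids, the per-patch pools of
    encounterable hosts (swap-removal for O(1) deletion), the set of
    parasitoids currently inside each patch (so their encounter clocks can
    be redrawn when a host dies there), the event heap, and the running
    :class:`~evotrap.outcomes.KillTally`.

    ``remove_matured_hosts`` is the single switch for the host-pool rule:
    by default hosts that complete their sensitive period stay encounterable
    (though unparasitizable) until the generation ends; setting it removes
    them from the pools at maturation.
    """

    __slots__ = ("p", "rng", "layout", "hosts1", "hosts2", "parasitoids",
                 "pools", "present", "heap", "seq", "unresolved", "tally",
                 "offspring", "clock", "remove_matured_hosts")

    def __init__(self, hosts1: list[HostIndividual], hosts2: list[HostIndividual],
                 genotypes: list[Genotype], p: ParameterSet, rng: SimRng,
                 remove_matured_hosts: bool = False):
        self.p = p
        self.rng = rng
        self.layout = PatchLayout(p.n1, p.n2)
        self.hosts1 = hosts1
        self.hosts2 = hosts2
        self.parasitoids = [ParasitoidState(g) for g in genotypes]
        self.remove_matured_hosts = remove_matured_hosts
        total = self.layout.total
        self.pools: list[list[HostIndividual]] = [[] for _ in range(total)]
        self.present: list[set[ParasitoidState]] = [set() for _ in range(total)]
        self.heap: list = []
        self.seq = 0
        self.tally = KillTally()
        self.offspring: list[Genotype] = []
        self.clock = 0.0
        for h in hosts1:
            self._add_to_pool(h)
        for h in hosts2:
            self._add_to_pool(h)
        self.unresolved = len(hosts1) + len(hosts2)
        for h in hosts1 + hosts2:
            self.push(h.maturation_time, EV_RESOLVE, h, h.version)
        tau_s = p.tau_s
        for a in self.parasitoids:
            self.push(rng.exponential(tau_s), EV_PATCH_FOUND, a, a.version)

    def _add_to_pool(self, h: HostIndividual) -> None:
        pool = self.pools[h.patch]
        h.pool_index = len(pool)
        pool.append(h)

    def remove_from_pool(self, h: HostIndividual) -> None:
        pool = self.pools[h.patch]
        last = pool.pop()
        if last is not h:
            pool[h.pool_index] = last
            last.pool_index = h.pool_index
        h.pool_index = -1

    def push(self, time: float, kind: int, actor, version: int) -> None:
        self.seq += 1
        heapq.heappush(self.heap, (time, self.seq, kind, actor, version))


def _schedule_in_patch(state: GenerationState, a: ParasitoidState, now: float) -> None:
    """Schedule the parasitoid's next in-patch event: encounter or give-up.

    The next encounter in a patch with m encounterable hosts arrives after
    an Exp(tau_e / m) interval; if that would land beyond the abandonment
    deadline (last encounter + tau_a), the give-up event is scheduled
    instead.  With an empty pool only the deadline remains.
    """
    p = state.p
    m = len(state.pools[a.patch])
    deadline = a.last_encounter_time + p.tau_a
    if m > 0:
        te = now + state.rng.exponential(p.tau_e / m)
        if te < deadline:
            state.push(te, EV_ENCOUNTER, a, a.version)
            return
    state.push(deadline, EV_LEAVE, a, a.version)


def _depart(state: GenerationState, a: ParasitoidState, now: float) -> None:
    """Leave the patch; recovery (one Exp(tau_r) per egg laid) then next search."""
    state.present[a.patch].discard(a)
    k = a.visit_investment
    a.leave_patch()
    rng = state.rng
    t = now
    tau_r = state.p.tau_r
    for _ in range(k):
        t += rng.exponential(tau_r)
    t += rng.exponential(state.p.tau_s)
    state.push(t, EV_PATCH_FOUND, a, a.version)


def run_generation(state: GenerationState, p: ParameterSet | None = None,
                   rng: SimRng | None = None) -> tuple[int, int, list[Genotype], KillTally]:
    """Run one generation's event loop to completion.

    Processes events in ``(time, sequence)`` order until no vulnerable host
    remains anywhere, then discards all pending parasitoid events (no
    further reproduction is possible).  Returns the surviving host counts
    per species, the emerged offspring genotypes (each already mutated at
    creation), and the kill tally.
    """
    p = p if p is not None else state.p
    rng = rng if rng is not None else state.rng
    heap = state.heap
    pools = state.pools
    present = state.present
    tally = state.tally
    eggs_laid = tally.eggs_laid
    offspring = state.offspring
    n1 = p.n1
    total = state.layout.total
    tau_s = p.tau_s
    heappop = heapq.heappop
    rng_exp = rng.exponential
    rng_random = rng.random
    rng_randrange = rng.randrange

    while state.unresolved > 0:
        if not heap:
            raise RuntimeError("event queue underflow with vulnerable hosts remaining")
        time, _, kind, actor, version = heappop(heap)
        if version != actor.version:
            continue  # superseded event
        state.clock = time

        if kind == EV_ENCOUNTER:
            pool = pools[actor.patch]
            host = pool[rng_randrange(len(pool))]
            if host in actor.visit_encountered:
                _depart(state, actor, time)  # second meeting: move on
                continue
            actor.visit_encountered.add(host)
            actor.last_encounter_time = time
            if host.fate == UNRESOLVED:
                old_best = host.best_completion
                lay_egg(actor, host, time, p, rng)
                eggs_laid[host.species - 1] += 1
                bc = host.best_completion
                if bc < old_best and bc < host.maturation_time:
                    host.version += 1
                    state.push(bc, EV_RESOLVE, host, host.version)
            _schedule_in_patch(state, actor, time)

        elif kind == EV_PATCH_FOUND:
            patch = rng_randrange(total)
            q = actor.genotype.q
            rej = -q if patch < n1 else q
            if rej > 0.0 and rng_random() < rej:
                state.push(time + rng_exp(tau_s), EV_PATCH_FOUND, actor, version)
            else:
                actor.enter_patch(patch, time)
                present[patch].add(actor)
                _schedule_in_patch(state, actor, time)

        elif kind == EV_RESOLVE:
            child = resolve_host_fate(actor, p, rng, tally)
            state.unresolved -= 1
            if child is not None:
                offspring.append(child)
            if actor.fate != SURVIVED or state.remove_matured_hosts:
                state.remove_from_pool(actor)
                watchers = present[actor.patch]
                if watchers:
                    # encounter clocks in this patch are stale: redraw (memoryless)
                    for a in list(watchers):
                        a.version += 1
                        _schedule_in_patch(state, a, time)

        else:  # EV_LEAVE
            _depart(state, actor, time)

    state.heap = []
    return tally.survived[0], tally.survived[1], offspring, tally


def _host_only_generation(H: tuple[int, int], p: ParameterSet,
                          rng: SimRng) -> tuple[int, int, KillTally]:
    """Generation with no parasitoids: every spawned host survives.

    The Ricker-Poisson spawn is drawn as usual; maturation times are
    irrelevant (nothing can intercept a host) so individuals are not
    instantiated.
    """
    tally = KillTally()
    s1 = int(np.sum(spawn_offspring(H[0], p, 1, rng)))
    s2 = int(np.sum(spawn_offspring(H[1], p, 2, rng)))
    tally.survived = [s1, s2]
    return s1, s2, tally


def run_replicate(p: ParameterSet, seed: int | np.random.SeedSequence | None = None,
                  replicate_index: int = 0,
                  remove_matured_hosts: bool = False,
                  progress=None) -> ReplicateResult:
    """Simulate one replicate: equilibrium initialisation, then all generations.

    Hosts start at their parasitoid-free equilibrium ``round(K ln r)``; the
    ``P0`` founding parasitoids all carry genotype (q=0, S=1) — pre-adapted
    to host 1, searching at random.  If the parasitoid population goes
    extinct the host-only dynamics continue to the horizon so the series
    stays rectangular, and the extinction generation is recorded.
    ``progress``, if given, is called as ``progress(generation, record)``
    after every generation.
    """
    validate_parameters(p)
    rng = SimRng(p.seed if seed is None else seed)
    (adults1, adults2), hosts1, hosts2 = initialize_hosts(p, rng)
    genotypes: list[Genotype] = [Genotype(0.0, 1)] * p.P0
    records: list[GenerationRecord] = []
    extinction: int | None = None
    survivors = (adults1, adults2)
    for gen in range(1, p.generations + 1):
        if gen > 1:
            if genotypes:
                c1 = spawn_offspring(survivors[0], p, 1, rng)
                c2 = spawn_offspring(survivors[1], p, 2, rng)
                hosts1 = sample_maturation_times(c1, p.tau_dH1, rng, 1, 0)
                hosts2 = sample_maturation_times(c2, p.tau_dH2, rng, 2, p.n1)
            else:
                s1, s2, tally = _host_only_generation(survivors, p, rng)
                records.append(record_generation(gen, genotypes, tally, s1, s2))
                survivors = (s1, s2)
                if progress is not None:
                    progress(gen, records[-1])
                continue
        state = GenerationState(hosts1, hosts2, genotypes, p, rng,
                                remove_matured_hosts=remove_matured_hosts)
        s1, s2, offspring, tally = run_generation(state)
        records.append(record_generation(gen, genotypes, tally, s1, s2))
        survivors = (s1, s2)
        if not offspring and genotypes and extinction is None:
            extinction = gen
        genotypes = offspring
        if progress is not None:
            progress(gen, records[-1])
    return ReplicateResult(params=p, records=records, replicate_index=replicate_index,
                           extinction_generation=extinction)


def run_grid(design: ExperimentDesign, keep_results: bool = True,
             remove_matured_hosts: bool = False) -> GridSummary:
    """Run every variant x replicate cell of an experimental design.

    Replicate seeds are spawned deterministically from each variant's own
    master seed (``SeedSequence(p.seed).spawn(replicates)``), so individual
    replicates can be reproduced in isolation and removing a variant leaves
    every other cell untouched.
    """
    results: dict[str, list[ReplicateResult]] = {}
    for label, p in design.variants:
        children = np.random.SeedSequence(p.seed).spawn(design.replicates)
        results[label] = [
            run_replicate(p, seed=children[i], replicate_index=i,
                          remove_matured_hosts=remove_matured_hosts)
            for i in range(design.replicates)
        ]
    table = summarize_replicates(design.variants, results)
    return GridSummary(table=table, replicates=design.replicates,
                       results=results if keep_results else None)
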