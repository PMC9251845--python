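# Methods

## The model

`evotrap` simulates a population of solitary koinobiont endo-parasitoids
foraging on two host species that live in separate patches: an original,
physiologically suitable host (species 1) and a novel invader (species 2)
that the founding parasitoids attack but cannot develop in — an
*evolutionary trap*. Generations are discrete and non-overlapping for hosts
and parasitoids alike; within a generation, behaviour unfolds in continuous
time as a stochastic event process.

**Hosts.** Each species is regulated globally by a stochastic Ricker map:
the offspring count in each of its `n_i` patches is Poisson with mean
`λ_i = (1/n_i) · r_i · H_i · exp(−H_i/K_i)`, where `H_i` is the adult count.
The parasitoid-free equilibrium is `H_i* = K_i · ln r_i` (1386 hosts per
species at the defaults `K = 1000`, `r = 4`). Each offspring is vulnerable
to parasitism during a sensitive developmental period of exponentially
distributed length (mean `τ_dH = 10`); a host whose period ends un-killed
matures and survives. First-order (exponential) development keeps the model
at one parameter per clock; the variation it creates in host vulnerability
is itself a stabilising ingredient of host–parasitoid dynamics.

**Parasitoids.** Females are time-limited, not egg-limited. Each carries two
clonally inherited haploid loci:

* `q ∈ [−1, +1]` — host preference. A female who finds a patch rejects it
  with probability `max(0, −q)` (species 1) or `max(0, +q)` (species 2);
  rejection costs only the next exponential search time (mean `τ_s`).
* `S ∈ {1, 2, 3}` — parasitization strategy: specialist on host 1,
  specialist on host 2, or generalist. Specialist eggs are physiologically
  compatible only with their own host; generalist eggs with both, at the
  price of slower development (`τ_dP3 > τ_dP1 = τ_dP2 = 20`).

Inside a patch with `m` encounterable hosts, encounters form the
superposition of `m` per-host Poisson processes (per-host mean interval
`τ_e = 0.02`); the female leaves on her second meeting with the same
individual during the visit, or after `τ_a = 1` time units without any
encounter. Every encounter with a still-vulnerable host yields an egg and
one unit of reproductive investment — females do not discriminate against
already-parasitized hosts, so superparasitism by conspecifics occurs. After
leaving she recovers for a Gamma-distributed pause (one exponential of mean
`τ_r = 0.5` per egg laid) before searching again. The recovery pause is the
handling time that makes the emergent per-host attack rate saturate with
host density (Holling type 2).

**Egg fate.** An egg's development time is exponential with a mean set by
the *mother's* strategy (maternal physiology), regardless of host species or
compatibility. The host dies iff some *qualifying* egg completes development
before the host's sensitive period ends; among several eggs the earliest
qualifying completion decides, and all other eggs are inviable (solitary
development). Because both clocks are exponential, a lone egg kills with
probability `τ_dH / (τ_dH + τ_dP)` — the generalist's developmental handicap
is exactly its longer `τ_dP3`. Two scenarios fix what an incompatible egg
can do:

* **Scenario 1** — incompatible attacks are inert: the egg never qualifies,
  the host is unharmed.
* **Scenario 2** — non-reproductive host mortality: every egg qualifies;
  an incompatible decider kills the host but yields no offspring.

**Genetics.** Offspring inherit the decider's parental genotype clonally,
with mutation applied once at emergence: with probability `μ_q` the
preference jumps by a standard-normal increment clamped to `[−1, +1]`
(the clamped kernel from `q = 0` has sd 0.718); with probability `μ_S` the
strategy moves 1→3, 2→3 (certainly) or 3→1/3→2 (each 1/2) — a specialist
can only reach the other specialist tactic through the generalist
intermediate. Under forced mutation the strategy chain's stationary
distribution is (1/4, 1/4, 1/2).

**Generation turnover.** The event loop runs until no vulnerable host
remains anywhere; emerged offspring replace the parental parasitoid
generation (`P(t+1)` = total emergences), surviving hosts set `H_i(t+1)`,
and the clock resets. Simulations start from host equilibrium
(`round(K ln r)` adults per species) and `P0 = 500` founding parasitoids,
all `(q = 0, S = 1)`: pre-adapted to host 1, searching at random.

## Event engine numerics

All waiting times are exponential, so the simulator is an event-driven
process in the Gillespie tradition: one priority queue ordered by
`(time, sequence number)` — the sequence number makes the order total and
deterministic even if two times serialise equally. Each parasitoid owns
exactly one pending event; each unresolved host owns one resolution event at
`min(maturation, earliest qualifying completion)`. Events invalidated by
state changes (an earlier decider egg; a host killed in a patch where other
females are searching) are superseded via per-actor version stamps and
skipped lazily when popped; because the clocks are memoryless, redrawing an
encounter interval from the moment the pool changed is exact, not an
approximation. Killed hosts leave the encounterable pool at their death
time — until then other females can waste eggs on a doomed host.

Two readings of the model are configurable or fixed here as package
decisions:

* **Matured hosts stay encounterable** (and count toward the
  second-encounter leaving rule) until the generation ends, but cannot be
  parasitized; they are removed at maturation instead when
  `remove_matured_hosts=True` is passed to the engine. Staying encounterable
  is the default because only hosts found *before the end of the sensitive
  period* can be parasitized, which implies later encounters happen.
* **The abandonment clock starts at patch entry** when no host has yet been
  encountered — the only available anchor in an empty patch.
* **Deciding egg = earliest completion**, not earliest laying: a later-laid
  egg that completes first decides the host's fate.
* Generations with no parasitoids skip the event loop: every spawned host
  survives by construction, so survivors are read off the Poisson spawn
  directly (exact, and the maturation draws that would affect nothing are
  not consumed).

Randomness comes from a per-replicate stream pair (stdlib generator for
scalar event draws, a numpy `Generator` for vectorised Poisson/exponential
batches) spawned deterministically from one `SeedSequence`, so any replicate
of any grid cell can be reproduced in isolation and identical seeds give
bit-identical output files.

## Parameters

| name | meaning | default |
|---|---|---|
| `n1, n2` | patches per host species | 20 |
| `r1, r2` | max per-capita host offspring | 4 |
| `K1, K2` | Ricker capacity coefficient | 1000 |
| `tau_dH1, tau_dH2` | mean host sensitive period | 10 |
| `tau_s` | mean patch search time (3 = resource-rich, 11 = sparse) | 7 |
| `tau_a` | patch abandonment threshold | 1 |
| `tau_e` | per-host mean encounter interval | 0.02 |
| `tau_r` | recovery time per egg | 0.5 |
| `tau_dP1, tau_dP2` | specialist offspring development mean | 20 |
| `tau_dP3` | generalist offspring development mean | 46.51 |
| `mu_q`, `mu_S` | mutation rates per reproductive event | 0.001, 0.01 |
| `P0` | founding parasitoid count | 500 |
| `generations` | horizon | 1000 |

All times share one abstract unit; none is calendar time. The evolutionary
experiments sweep `tau_s ∈ {3, 7, 11}` and
`tau_dP3 ∈ {46.51 … 42.55}` (generalist efficiency `tau_dP1/tau_dP3` from
0.43 to 0.47), under each scenario and mutation regime (`mu_S` only, or
`mu_S` and `mu_q`). Defaults take the middle search time and the harshest
generalist trade-off.

## What the tests and the acceptance script simulate

The statistical test suite and `scripts/acceptance.py` run the full model at
desk scale — `K = 200`, `n = 8` patches per species, `P0 = 100`, 400–500
generations, 6–10 replicates per scenario — which keeps the entire suite in
minutes on one core while preserving every mechanism (the habitat is
smaller, not the behaviour). One caveat matters when reading desk-scale
results: under scenario 1 the novel-host specialist robustly arises through
the generalist intermediate, but the scenario-2 suppression of that
specialist is a *weak-selection* effect — once non-reproductive killing has
depleted host 2, the per-capita fitnesses of the three strategies nearly
equalize, and in a parasitoid population of only a couple hundred
individuals genetic drift can carry the novel-host specialist across the
generalist valley anyway. Small-habitat runs therefore understate the
host-range conservation seen at full habitat size; figure-scale
conclusions need the full `K = 1000`, `n = 20`, 1000-generation,
30-replicate runs via the CLI.

Operator-level distributions are checked against independent oracles: exact
closed forms (race probability, rejection rule, Ricker fixed point,
transition-matrix eigenvector), quadrature (clamped mutation kernel
moments), and direct Monte-Carlo re-implementations (birthday-problem
distinct-encounter count, search-reject loop).

## Known limitations

* Haploid clonal genetics — no haplodiploidy, sex, recombination, or
  multilocus traits; host preference and performance evolve as two
  independent loci.
* Hosts do not evolve: no counter-resistance arms race, and no graded
  virulence.
* No egg limitation, learning, or patch-quality assessment by females.
* Hosts of the two species never compete; `r` and `K` are constant in time.
* Exponential clocks everywhere: development, maturation, search and
  encounter processes all first-order. Heavier-tailed or age-structured
  waiting times would change quantitative rates, though the race structure
  is generic.
* A generation's length is emergent (the time until the last host leaves
  its vulnerable window), not a configurable constant.
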