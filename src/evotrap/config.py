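"""Model parameters, validation, and derived reference quantities.

All constants of the two-host/one-parasitoid model live in
:class:`ParameterSet`.  Time is abstract (no unit system): every ``tau_*``
parameter is a mean of an exponential waiting-time distribution expressed in
model time units.  The defaults are the baseline simulation conditions; the
parameters that the evolutionary experiments sweep (``tau_s``, ``tau_dP3``,
``mu_q``, ``mu_S``, ``scenario``) are varied through :class:`ExperimentDesign`.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from typing import Any, Sequence

__all__ = [
    "ParameterSet",
    "ExperimentDesign",
    "ParameterError",
    "validate_parameters",
    "equilibrium_density",
    "generalist_efficiency",
    "load_parameters",
]


class ParameterError(ValueError):
    """A model parameter violates one of its invariants."""


@dataclass(frozen=True)
class ParameterSet:
    """All constants of the model plus scenario flag and master seed.

    Attributes
    ----------
    n1, n2
        Number of habitat patches for host species 1 and 2.
    r1, r2
        Maximum per-capita host offspring production rates (must exceed 1 for
        a positive equilibrium).
    K1, K2
        Ricker carrying-capacity coefficients; the parasitoid-free host
        equilibrium is ``K * ln(r)``.
    tau_dH1, tau_dH2
        Mean length of the host's sensitive (parasitizable) developmental
        period; maturation times are exponential with this mean.
    tau_s
        Mean time for a searching parasitoid to locate a host patch.
    tau_a
        Patch-abandonment threshold: time since the last host encounter after
        which the parasitoid gives up on the patch.
    tau_e
        Mean interval between encounters with one given host individual.
    tau_r
        Mean recovery time per unit of reproductive investment (egg laid).
    tau_dP1, tau_dP2, tau_dP3
        Mean development time of parasitoid offspring when the mother's
        strategy is S=1, 2 (specialists) or 3 (generalist).  The generalist's
        broader host range trades off against slower development, hence
        ``tau_dP3 > tau_dP1``.
    mu_q, mu_S
        Mutation probabilities per reproductive event for host preference q
        and parasitization strategy S.
    P0
        Initial parasitoid population size.
    generations
        Number of discrete, non-overlapping generations to simulate.
    scenario
        1: an incompatible attack leaves the host unharmed;
        2: an incompatible attack kills the host without producing offspring
        (non-reproductive host mortality).
    seed
        Master RNG seed; replicate streams are spawned from it.
    """

    n1: int = 20
    n2: int = 20
    r1: float = 4.0
    r2: float = 4.0
    K1: float = 1000.0
    K2: float = 1000.0
    tau_dH1: float = 10.0
    tau_dH2: float = 10.0
    tau_s: float = 7.0
    tau_a: float = 1.0
    tau_e: float = 0.02
    tau_r: float = 0.5
    tau_dP1: float = 20.0
    tau_dP2: float = 20.0
    tau_dP3: float = 46.51
    mu_q: float = 0.001
    mu_S: float = 0.01
    P0: int = 500
    generations: int = 1000
    scenario: int = 1
    seed: int = 0

    def replace(self, **changes: Any) -> "ParameterSet":
        """Return a validated copy with the given fields replaced."""
        return validate_parameters(dataclasses.replace(self, **changes))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def validate_parameters(p: ParameterSet) -> ParameterSet:
    """Check every :class:`ParameterSet` invariant; return ``p`` unchanged.

    Raises
    ------
    ParameterError
        Naming the first violated invariant.
    """
    for name in ("tau_dH1", "tau_dH2", "tau_s", "tau_a", "tau_e", "tau_r",
                 "tau_dP1", "tau_dP2", "tau_dP3"):
        if not getattr(p, name) > 0:
            raise ParameterError(f"{name} must be strictly positive, got {getattr(p, name)}")
    for name in ("r1", "r2"):
        if not getattr(p, name) > 1:
            raise ParameterError(f"{name} must exceed 1 (no positive equilibrium otherwise), "
                                 f"got {getattr(p, name)}")
    for name in ("K1", "K2"):
        if not getattr(p, name) > 0:
            raise ParameterError(f"{name} must be positive, got {getattr(p, name)}")
    for name in ("n1", "n2"):
        if getattr(p, name) < 1:
            raise ParameterError(f"{name} must be at least 1, got {getattr(p, name)}")
    for name in ("mu_q", "mu_S"):
        if not 0.0 <= getattr(p, name) <= 1.0:
            raise ParameterError(f"{name} is a probability and must lie in [0, 1], "
                                 f"got {getattr(p, name)}")
    if p.scenario not in (1, 2):
        raise ParameterError(f"scenario must be 1 or 2, got {p.scenario}")
    if p.P0 < 0:
        raise ParameterError(f"P0 must be non-negative, got {p.P0}")
    if p.generations < 1:
        raise ParameterError(f"generations must be at least 1, got {p.generations}")
    if not p.tau_dP3 > p.tau_dP1:
        raise ParameterError(
            f"tau_dP3 ({p.tau_dP3}) must exceed tau_dP1 ({p.tau_dP1}): generalist "
            "offspring develop more slowly than specialist offspring")
    return p


def equilibrium_density(K: float, r: float) -> float:
    """Parasitoid-free host equilibrium ``K * ln(r)`` of the Ricker map.

    Raises
    ------
    ParameterError
        If ``r <= 1`` (no positive equilibrium) or ``K <= 0``.
    """
    if r <= 1:
        raise ParameterError(f"no positive equilibrium for growth rate r = {r} <= 1")
    if K <= 0:
        raise ParameterError(f"carrying capacity K must be positive, got {K}")
    return K * math.log(r)


def generalist_efficiency(p: ParameterSet) -> float:
    """Ratio ``tau_dP1 / tau_dP3`` labelling the generalist's developmental cost.

    1 would mean generalists develop as fast as specialists (excluded by
    validation); smaller values mean a harsher specialist-generalist trade-off.
    """
    return p.tau_dP1 / p.tau_dP3


@dataclass(frozen=True)
class ExperimentDesign:
    """A labelled collection of parameter variants with a replicate count."""

    variants: Sequence[tuple[str, ParameterSet]] = field(default_factory=list)
    replicates: int = 30
    label: str = "experiment"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError(f"replicates must be at least 1, got {self.replicates}")
        labels = [name for name, _ in self.variants]
        if len(set(labels)) != len(labels):
            raise ParameterError("variant labels must be unique")
        for _, p in self.variants:
            validate_parameters(p)


def load_parameters(path: str | None = None,
                    overrides: dict[str, Any] | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a TOML file plus overrides.

    The file is a flat key/value TOML document whose keys are exactly the
    :class:`ParameterSet` field names.  ``overrides`` (e.g. from CLI flags)
    win over file values, which win over defaults.
    """
    values: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            loaded = tomllib.load(fh)
        unknown = set(loaded) - {f.name for f in dataclasses.fields(ParameterSet)}
        if unknown:
            raise ParameterError(f"unknown parameter keys in {path}: {sorted(unknown)}")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    return validate_parameters(ParameterSet(**values))
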