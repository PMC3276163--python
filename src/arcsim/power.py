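"""Detection power for unlinked allorecognition modifiers.

The breeding-design logic: progeny homozygous for an inbred ARC haplotype
but carrying wild-type genetic background are assayed against an
allocompatible inbred tester.  Under the null (no modifier) every such
progeny fuses; any departure from fusion in any individual is evidence for a
modifier.  A design fails to detect a real dominant modifier only if no
tested individual inherited it, so the miss probability is the product of
per-individual non-carriage probabilities:

* backcross or F2-incross progeny carry 50% wild background, hence carriage
  probability 0.5 per individual and miss probability (0.5)^n;
* under an explicit heterozygous-carrier founder model, an F2-incross
  progeny misses the modifier with probability (3/4) per transmission
  opportunity, and a composite design with n F2 and m terminal-population
  (25%-background) individuals has miss probability (0.75)^(2n+m).

Both parameterizations are expressible here because a design is just an
explicit list of per-individual carriage probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ArcsimError, ConfigError, FusibilityOutcome
from .simulate import Inheritance, ModifierModel, CarriageScheme, ROLE_CARRIAGE


class RoleError(ArcsimError):
    """Unknown pedigree role."""


ROLES = ("backcross_progeny", "f2_incross_progeny", "terminal_25pct")


def carriage_probability(role: str, scheme: CarriageScheme) -> float:
    """Modifier-carriage probability of one progeny, by pedigree role.

    ``GENOME_FRACTION`` equates carriage probability with wild-background
    genome fraction (0.5 for backcross and F2-incross progeny, 0.25 for
    terminal populations).  ``CARRIER_TRANSMISSION`` tracks Mendelian
    transmission from a single-copy carrier founder, which gives F2-incross
    progeny 1 - (3/4)^2 = 0.4375 instead of 0.5; the other roles coincide.
    """
    table = ROLE_CARRIAGE[CarriageScheme(scheme)]
    try:
        return table[role]
    except KeyError:
        raise RoleError(
            f"unknown pedigree role {role!r}; expected one of {ROLES}"
        ) from None


@dataclass(frozen=True)
class DetectionDesign:
    """A breeding design: per-individual carriage probabilities and alpha."""

    individuals: tuple[tuple[str, float], ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "individuals", tuple(self.individuals))
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        for ind_id, c in self.individuals:
            if not 0.0 <= c <= 1.0:
                raise ConfigError(
                    f"carriage probability {c} of {ind_id!r} outside [0, 1]"
                )

    @classmethod
    def uniform(cls, n: int, c: float, alpha: float = 0.05, prefix: str = "ind") -> "DetectionDesign":
        return cls(tuple((f"{prefix}-{i + 1}", c) for i in range(n)), alpha)

    @classmethod
    def from_roles(
        cls,
        roles: Sequence[str],
        scheme: CarriageScheme = CarriageScheme.CARRIER_TRANSMISSION,
        alpha: float = 0.05,
    ) -> "DetectionDesign":
        return cls(
            tuple(
                (f"{role}-{i + 1}", carriage_probability(role, scheme))
                for i, role in enumerate(roles)
            ),
            alpha,
        )

    @property
    def carriage(self) -> np.ndarray:
        return np.array([c for _, c in self.individuals])


@dataclass(frozen=True)
class PowerResult:
    """Miss probability and detection power of a design."""

    p_miss: float
    detect_power: float
    reject_null: bool
    degenerate: bool = False


def miss_probability(design: DetectionDesign) -> PowerResult:
    """Probability that no tested individual carries the modifier.

    p_miss = prod_i (1 - c_i).  The null hypothesis of a present,
    fully-penetrant dominant modifier is rejected when p_miss < alpha: had
    one existed the design would almost surely have seen a departure from
    fusion.  An empty design is degenerate (p_miss = 1, flagged).
    """
    if not design.individuals:
        return PowerResult(1.0, 0.0, False, degenerate=True)
    p_miss = float(np.prod(1.0 - design.carriage))
    return PowerResult(p_miss, 1.0 - p_miss, p_miss < design.alpha)


def min_n(alpha: float, c: float) -> int:
    """Smallest n with (1 - c)^n < alpha: individuals needed for detection.

    Exact integer by direct search; monotone decreasing in c and increasing
    as alpha shrinks.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie in (0, 1)")
    if c <= 0.0:
        raise ConfigError("carriage probability 0 can never reach alpha")
    if c >= 1.0:
        return 1
    n = 1
    p = 1.0 - c
    while p >= alpha:
        n += 1
        p *= 1.0 - c
    return n


def detect_modifier(
    observed: Sequence[FusibilityOutcome], expected: FusibilityOutcome
) -> tuple[bool | None, list[int]]:
    """The all-or-nothing decision rule on assay outcomes.

    Positive iff any observed outcome departs from the null-model
    expectation; returns ``(decision, departing_indices)``.  Empty
    observations are inconclusive (decision None).
    """
    if len(observed) == 0:
        return None, []
    departing = [i for i, o in enumerate(observed) if o is not expected]
    return bool(departing), departing


def empirical_power(
    design: DetectionDesign,
    model: ModifierModel,
    reps: int,
    seed: int,
) -> float:
    """Monte-Carlo detection frequency of a design under a modifier model.

    Each replicate draws carriage per individual (Bernoulli of its carriage
    probability, one allele copy when carried), applies the expression rule
    and penetrance, and scores detection by the all-or-nothing rule.  For
    penetrance 1 this converges to 1 - p_miss.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    c = design.carriage
    if c.size == 0:
        return 0.0
    carried = rng.random((reps, c.size)) < c
    if model.inheritance is Inheritance.RECESSIVE:
        # single transmitted copies never express a recessive modifier
        expressed = np.zeros_like(carried)
    else:
        expressed = carried & (rng.random((reps, c.size)) < model.penetrance)
    detected = expressed.any(axis=1)
    return float(detected.mean())
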