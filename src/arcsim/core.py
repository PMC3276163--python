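"""Domain model for the *Hydractinia* allorecognition complex (ARC).

The ARC is a chromosomal interval containing the two allodeterminant loci
*alr1* and *alr2* plus a set of linked molecular markers.  A colony's
fusibility phenotype toward another colony is predicted by allele sharing
at the two *alr* loci:

* alleles shared at both loci  -> permanent fusion
* alleles shared at neither    -> rejection
* alleles shared at exactly one -> transitory fusion, subtyped by the locus
  at which the alleles ARE shared

This module holds the marker panel, haplotype and genotype types and the
genotype -> fusibility classification rule.  Allele identity is exact symbol
equality; sharing is evaluated per locus over all four haplotype pairings,
so trans configurations count (recombinant haplotypes produce congenic-style
transitory fusion).  An unlinked modifier locus is carried on the genotype
but deliberately ignored by the classifier: its phenotypic effect belongs to
the assay model in :mod:`arcsim.simulate`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

ALR_LOCI = ("alr1", "alr2")

_PREFIX_RE = re.compile(r"^(\d+)")


class ArcsimError(Exception):
    """Base class for all arcsim errors."""


class InvalidGenotypeError(ArcsimError):
    """A genotype is structurally invalid (e.g. missing alr allele)."""


class ProvenanceError(ArcsimError):
    """A marker allele cannot be traced to any founder haplotype."""


class ConfigError(ArcsimError):
    """A configuration value is invalid."""


class FusibilityOutcome(Enum):
    """The four colony-contact phenotypes."""

    FUSION = "fusion"
    TRANSITORY_FUSION_ALR1 = "transitory_fusion_alr1"
    TRANSITORY_FUSION_ALR2 = "transitory_fusion_alr2"
    REJECTION = "rejection"


def marker_prefix(marker: str) -> str:
    """Locus-group prefix of a marker name: the digits before the first letter.

    Markers sharing a prefix (e.g. 194m6 and 194c17) are closely linked
    relative to the size of the ARC and are treated as one locus for mapping.
    """
    m = _PREFIX_RE.match(marker)
    if not m:
        raise ConfigError(f"marker {marker!r} has no numeric prefix")
    return m.group(1)


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered panel of ARC markers with optional reference positions.

    Parameters
    ----------
    markers:
        Marker names in chromosomal order, e.g.
        ``("194m6", "18m1", "28m6", "174m4")``.
    positions_cM:
        Optional map marker -> position on a reference map; must be weakly
        increasing in panel order.
    """

    markers: tuple[str, ...]
    positions_cM: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if len(set(self.markers)) != len(self.markers):
            raise ConfigError("marker names must be unique")
        if not self.markers:
            raise ConfigError("marker panel must not be empty")
        for m in self.markers:
            marker_prefix(m)  # raises if prefix empty
        if self.positions_cM is not None:
            pos = [self.positions_cM[m] for m in self.markers]
            if any(p < 0 for p in pos):
                raise ConfigError("marker positions must be non-negative")
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise ConfigError("marker positions must be weakly increasing")

    @property
    def prefix_of(self) -> dict[str, str]:
        return {m: marker_prefix(m) for m in self.markers}

    @property
    def n_intervals(self) -> int:
        return len(self.markers) - 1

    def index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise ConfigError(f"marker {marker!r} not in panel") from None


@dataclass(frozen=True)
class Haplotype:
    """One ARC chromosome: marker alleles plus the alr1 and alr2 alleles.

    Haplotypes are labeled by founder letter (f, r, c, d, a, b, i, r2);
    recombinant haplotypes get a composite label built from their donors.
    """

    label: str
    marker_alleles: Mapping[str, str]
    alr1_allele: str
    alr2_allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_alleles", dict(self.marker_alleles))
        if not self.alr1_allele or not self.alr2_allele:
            raise InvalidGenotypeError(
                f"haplotype {self.label!r} is missing an alr allele symbol"
            )
        if any(not a for a in self.marker_alleles.values()):
            raise InvalidGenotypeError(
                f"haplotype {self.label!r} has an empty marker allele symbol"
            )

    def alr_allele(self, locus: str) -> str:
        if locus == "alr1":
            return self.alr1_allele
        if locus == "alr2":
            return self.alr2_allele
        raise ConfigError(f"unknown alr locus {locus!r}")


def founder_haplotype(label: str, panel: MarkerPanel, allele: str | None = None) -> Haplotype:
    """Intact founder haplotype whose every allele symbol is the founder letter.

    A convenient constructor for the common case where alleles are named
    after the haplotype (allele ``f`` at every marker of haplotype ``f``).
    """
    a = allele if allele is not None else label
    return Haplotype(
        label=label,
        marker_alleles={m: a for m in panel.markers},
        alr1_allele=a,
        alr2_allele=a,
    )


@dataclass(frozen=True)
class ColonyGenotype:
    """A diploid colony: an unordered pair of ARC haplotypes plus the count
    of modifier alleles (0-2) at one hypothetical unlinked locus."""

    id: str
    haplotypes: tuple[Haplotype, Haplotype]
    modifier_copies: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "haplotypes", tuple(self.haplotypes))
        if len(self.haplotypes) != 2:
            raise InvalidGenotypeError("a colony genotype carries exactly two haplotypes")
        if not 0 <= self.modifier_copies <= 2:
            raise InvalidGenotypeError("modifier_copies must be 0, 1 or 2")

    def alr_alleles(self, locus: str) -> set[str]:
        return {h.alr_allele(locus) for h in self.haplotypes}

    @property
    def labels(self) -> tuple[str, str]:
        return (self.haplotypes[0].label, self.haplotypes[1].label)

    def describe(self) -> str:
        return f"ARC-{self.haplotypes[0].label}/{self.haplotypes[1].label}"


def shared_alr_loci(a: ColonyGenotype, b: ColonyGenotype) -> set[str]:
    """Loci in {alr1, alr2} at which the two colonies share >=1 allele symbol.

    Sharing is assessed per locus over all four pairwise haplotype
    comparisons, i.e. trans sharing counts.  Symmetric in its arguments.
    """
    shared = set()
    for locus in ALR_LOCI:
        if a.alr_alleles(locus) & b.alr_alleles(locus):
            shared.add(locus)
    return shared


def classify_fusibility(a: ColonyGenotype, b: ColonyGenotype) -> FusibilityOutcome:
    """Predict the contact phenotype of two colonies from their alr genotypes.

    The rule is the null model without modifiers: sharing at both loci gives
    fusion, at neither gives rejection, and at exactly one gives transitory
    fusion subtyped by the shared locus.  Symmetric, and every genotype
    fuses with itself.
    """
    shared = shared_alr_loci(a, b)
    if shared == {"alr1", "alr2"}:
        return FusibilityOutcome.FUSION
    if shared == {"alr1"}:
        return FusibilityOutcome.TRANSITORY_FUSION_ALR1
    if shared == {"alr2"}:
        return FusibilityOutcome.TRANSITORY_FUSION_ALR2
    return FusibilityOutcome.REJECTION


MISSING = "-"


def format_pair(a: str, b: str) -> str:
    """Encode an unordered allele pair as an ``x/y`` string.

    Pairs are unordered (``f/d`` is the same genotype as ``d/f``) and are
    normalized lexicographically so that equal genotypes encode identically.
    """
    x, y = sorted((a, b))
    return f"{x}/{y}"


def parse_pair(s: str) -> tuple[str, str] | None:
    """Decode an ``x/y`` allele-pair string; ``-`` means missing (None)."""
    s = s.strip()
    if s == MISSING or s == "":
        return None
    parts = s.split("/")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ArcsimError(f"malformed allele pair {s!r}")
    x, y = sorted(parts)
    return (x, y)


def is_recombinant_over_arc(
    h: Haplotype, founders: Sequence[Haplotype], panel: MarkerPanel
) -> bool:
    """True iff the marker alleles of ``h`` are not all attributable to a
    single founder haplotype.

    Raises :class:`ProvenanceError` if any allele of ``h`` is not carried by
    any founder at that marker.
    """
    if not founders:
        raise ProvenanceError("no founder haplotypes supplied")
    compatible = set(range(len(founders)))
    for m in panel.markers:
        allele = h.marker_alleles.get(m)
        if allele is None:
            continue
        carriers = {
            i for i, f in enumerate(founders) if f.marker_alleles.get(m) == allele
        }
        if not carriers:
            raise ProvenanceError(
                f"allele {allele!r} at marker {m} not found in any founder"
            )
        compatible &= carriers
    return not compatible
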