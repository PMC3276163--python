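"""Seeded simulation of gametes, crosses, pedigrees and fusion assays.

The simulator emulates the structure of the mapping-population genotype data
used to study the *Hydractinia* ARC: testcross-type progeny genotyped at a
handful of linked ARC markers segregating 1:1, with recombination between
adjacent markers at configurable map distances, plus an optional unlinked
biallelic modifier locus.

Meiosis follows the no-interference model: the parental haplotype donating
the first marker is chosen fairly, and an independent crossover indicator is
drawn for every inter-marker interval with probability equal to the inverse
map function of the interval's distance.  The *alr1* allele travels with the
first marker of the panel and *alr2* with the last (the two loci bracket the
marker interval), so recombinant gametes can carry discordant alr alleles.

All randomness flows from a single seed via ``numpy.random.Generator``
streams; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ArcsimError,
    ColonyGenotype,
    ConfigError,
    FusibilityOutcome,
    Haplotype,
    MarkerPanel,
    MISSING,
    classify_fusibility,
    format_pair,
)
from .mapping import inverse_map_function


class SpecError(ArcsimError):
    """A pedigree specification is inconsistent."""


class Inheritance(Enum):
    DOMINANT = "dominant"
    CODOMINANT = "codominant"
    INCOMPLETE = "incomplete"
    RECESSIVE = "recessive"


class CarriageScheme(Enum):
    """How wild-type modifier carriage enters the pedigree.

    ``GENOME_FRACTION`` paints carriage directly onto progeny with
    probability equal to their wild-background genome fraction (0.5 for
    backcross/F2 progeny, 0.25 for terminal populations).
    ``CARRIER_TRANSMISSION`` models an explicitly heterozygous wild founder
    and Mendelian transmission of the modifier allele, so an F2-incross
    progeny misses the modifier with probability (3/4) per incross — the
    arithmetic behind a (0.75)^(2n+m) composite miss probability.
    """

    GENOME_FRACTION = "genome_fraction"
    CARRIER_TRANSMISSION = "carrier_transmission"


@dataclass(frozen=True)
class ModifierModel:
    """A hypothetical unlinked allorecognition modifier.

    Expressed carriers show a departure from the fusion phenotype their alr
    genotype predicts.  Dominant/codominant/incompletely dominant modifiers
    express with one allele copy; recessive require two.
    """

    inheritance: Inheritance = Inheritance.DOMINANT
    penetrance: float = 1.0
    carriage_scheme: CarriageScheme = CarriageScheme.CARRIER_TRANSMISSION

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigError("penetrance must lie in [0, 1]")

    def expresses(self, copies: int) -> bool:
        if self.inheritance is Inheritance.RECESSIVE:
            return copies == 2
        return copies >= 1


NO_MODIFIER = ModifierModel(penetrance=0.0)

# Per-individual modifier-carriage probability by pedigree role.  Backcross
# and F2-incross progeny sample half the wild genetic background; terminal
# populations a quarter.  Under an explicit single-copy-carrier founder the
# F2-incross figure becomes 1 - (3/4)^2 (two independent transmission
# opportunities), the others coincide.
ROLE_CARRIAGE = {
    CarriageScheme.GENOME_FRACTION: {
        "backcross_progeny": 0.5,
        "f2_incross_progeny": 0.5,
        "terminal_25pct": 0.25,
    },
    CarriageScheme.CARRIER_TRANSMISSION: {
        "backcross_progeny": 0.5,
        "f2_incross_progeny": 1.0 - 0.75**2,
        "terminal_25pct": 0.25,
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Seed, per-interval map distances and map function for a simulation."""

    seed: int
    map_distances_cM: tuple[float, ...]
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        object.__setattr__(self, "map_distances_cM", tuple(self.map_distances_cM))
        if any(d < 0 for d in self.map_distances_cM):
            raise ConfigError("map distances must be non-negative")

    def interval_recomb_fractions(self, panel: MarkerPanel) -> np.ndarray:
        if len(self.map_distances_cM) != panel.n_intervals:
            raise ConfigError(
                f"{len(self.map_distances_cM)} interval distances for a panel "
                f"with {panel.n_intervals} intervals"
            )
        return np.array(
            [inverse_map_function(d, self.map_function) for d in self.map_distances_cM]
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# gametes
# ---------------------------------------------------------------------------

def gamete_origins(
    parent: ColonyGenotype,
    panel: MarkerPanel,
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """Haplotype-of-origin matrix for ``n`` gametes: shape (n, n_markers + 2).

    Entry 0 or 1 names which parental haplotype donated each locus.  The
    first and last columns are the *alr1* and *alr2* origins (co-segregating
    with the first and last marker respectively); columns 1..m are the
    markers in panel order.
    """
    r = config.interval_recomb_fractions(panel)
    first = rng.integers(0, 2, size=n)
    xo = rng.random((n, panel.n_intervals)) < r
    marker_org = (first[:, None] + np.concatenate(
        [np.zeros((n, 1), dtype=int), np.cumsum(xo, axis=1)], axis=1
    )) % 2
    return np.concatenate(
        [marker_org[:, :1], marker_org, marker_org[:, -1:]], axis=1
    )


def _haplotype_from_origins(
    parent: ColonyGenotype, panel: MarkerPanel, origins: np.ndarray
) -> Haplotype:
    """Build the gamete haplotype named by one row of the origin matrix."""
    h = parent.haplotypes
    alr1 = h[origins[0]].alr1_allele
    marker_alleles = {
        m: h[origins[1 + j]].marker_alleles[m] for j, m in enumerate(panel.markers)
    }
    alr2 = h[origins[-1]].alr2_allele
    donor_labels = [h[origins[1 + j]].label for j in range(len(panel.markers))]
    runs = [donor_labels[0]]
    for lab in donor_labels[1:]:
        if lab != runs[-1]:
            runs.append(lab)
    label = runs[0] if len(runs) == 1 else "+".join(runs)
    return Haplotype(label, marker_alleles, alr1, alr2)


def draw_gamete(
    parent: ColonyGenotype,
    panel: MarkerPanel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Haplotype:
    """Draw one meiotic gamete haplotype from ``parent``.

    Homozygous parents yield their haplotype unchanged; heterozygous parents
    yield an intact parental haplotype unless a crossover indicator fires.
    The unlinked modifier is not part of the chromosome and is transmitted
    separately (see :func:`simulate_cross`).
    """
    origins = gamete_origins(parent, panel, config, rng, 1)[0]
    return _haplotype_from_origins(parent, panel, origins)


# ---------------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------------

def genotype_table(
    progeny: Sequence[ColonyGenotype],
    panel: MarkerPanel,
    population: str = "pop",
    include_modifier: bool = True,
) -> pd.DataFrame:
    """Tabulate colonies as individuals x markers with ``x/y`` pair calls."""
    rows = []
    for g in progeny:
        h0, h1 = g.haplotypes
        row: dict[str, object] = {"individual": g.id, "population": population}
        for m in panel.markers:
            row[m] = format_pair(h0.marker_alleles[m], h1.marker_alleles[m])
        if include_modifier:
            row["modifier"] = g.modifier_copies
        rows.append(row)
    cols = ["individual", "population", *panel.markers]
    if include_modifier:
        cols.append("modifier")
    return pd.DataFrame(rows, columns=cols)


def simulate_cross(
    p1: ColonyGenotype,
    p2: ColonyGenotype,
    n: int,
    panel: MarkerPanel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    population: str = "pop",
    id_prefix: str | None = None,
) -> tuple[list[ColonyGenotype], pd.DataFrame]:
    """Cross two colonies and return ``n`` progeny plus their genotype table.

    Each progeny receives one independent gamete per parent; the modifier
    allele is unlinked and each parent transmits one with probability
    ``modifier_copies / 2``.
    """
    if n < 1:
        raise ConfigError("progeny count must be >= 1")
    if rng is None:
        rng = config.rng()
    prefix = id_prefix if id_prefix is not None else population
    org1 = gamete_origins(p1, panel, config, rng, n)
    org2 = gamete_origins(p2, panel, config, rng, n)
    mod1 = rng.random(n) < p1.modifier_copies / 2.0
    mod2 = rng.random(n) < p2.modifier_copies / 2.0
    progeny = []
    for i in range(n):
        g1 = _haplotype_from_origins(p1, panel, org1[i])
        g2 = _haplotype_from_origins(p2, panel, org2[i])
        progeny.append(
            ColonyGenotype(
                id=f"{prefix}-{i + 1}",
                haplotypes=(g1, g2),
                modifier_copies=int(mod1[i]) + int(mod2[i]),
            )
        )
    return progeny, genotype_table(progeny, panel, population)


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeNode:
    """One pedigree node: a founder colony or a cross between two nodes.

    ``parents`` are node ids; when a parent node is a progeny population,
    ``parent_labels`` may name the unordered haplotype-label pair the chosen
    mate must carry (the real pedigrees select specific genotypes, e.g. an
    ARC-r/a F1).  Without a selector the first individual is used.
    """

    id: str
    founder: ColonyGenotype | None = None
    parents: tuple[str, str] | None = None
    parent_labels: tuple[frozenset | None, frozenset | None] = (None, None)
    n: int = 1
    role: str | None = None  # modifier-carriage role, see ROLE_CARRIAGE
    map_distances_cM: tuple[float, ...] | None = None  # per-node override

    def __post_init__(self) -> None:
        if (self.founder is None) == (self.parents is None):
            raise SpecError(
                f"node {self.id!r} must have exactly one of founder / parents"
            )
        if self.n < 1:
            raise SpecError(f"node {self.id!r} has non-positive progeny count")


@dataclass(frozen=True)
class PedigreeSpec:
    """An acyclic set of pedigree nodes keyed by id."""

    nodes: tuple[PedigreeNode, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise SpecError("duplicate node ids")
        known = set()
        for node in self.nodes:
            if node.parents is not None:
                for p in node.parents:
                    if p not in known:
                        raise SpecError(
                            f"node {node.id!r} references undefined parent {p!r}"
                        )
            known.add(node.id)


@dataclass
class SimulatedPopulation:
    """Progeny of one pedigree node plus bookkeeping used downstream."""

    genotypes: list[ColonyGenotype]
    table: pd.DataFrame
    wild_fraction: float


def _pick_mate(
    pop: SimulatedPopulation, labels: frozenset | None, node_id: str
) -> ColonyGenotype:
    if labels is None:
        return pop.genotypes[0]
    for g in pop.genotypes:
        if frozenset(g.labels) == labels:
            return g
    raise SpecError(
        f"no individual with haplotype labels {set(labels)} available to mate "
        f"into node {node_id!r}"
    )


def simulate_pedigree(
    spec: PedigreeSpec,
    panel: MarkerPanel,
    config: SimulationConfig,
    modifier: ModifierModel = NO_MODIFIER,
    wild_founders: frozenset[str] = frozenset(),
) -> dict[str, SimulatedPopulation]:
    """Simulate every node of a pedigree; returns populations keyed by id.

    ``wild_founders`` names the founder nodes carrying wild-type genetic
    background.  Under ``CARRIER_TRANSMISSION`` those founders are single-copy
    modifier carriers and the allele segregates Mendelianly; under
    ``GENOME_FRACTION`` carriage is painted onto each progeny with
    probability equal to its wild-background genome fraction.  Each node gets
    a deterministic RNG sub-stream derived from the config seed, so adding a
    node does not perturb the others.
    """
    results: dict[str, SimulatedPopulation] = {}
    for node in spec.nodes:
        # stable per-node sub-stream (zlib.crc32 is process-invariant,
        # unlike builtin str hashing)
        rng = np.random.default_rng([config.seed, zlib.crc32(node.id.encode())])
        if node.founder is not None:
            g = node.founder
            wild = 1.0 if node.id in wild_founders else 0.0
            if (
                wild
                and modifier is not NO_MODIFIER
                and modifier.carriage_scheme is CarriageScheme.CARRIER_TRANSMISSION
            ):
                g = ColonyGenotype(g.id, g.haplotypes, modifier_copies=1)
            results[node.id] = SimulatedPopulation(
                [g], genotype_table([g], panel, node.id), wild
            )
            continue
        pa, pb = node.parents  # type: ignore[misc]
        mate_a = _pick_mate(results[pa], node.parent_labels[0], node.id)
        mate_b = _pick_mate(results[pb], node.parent_labels[1], node.id)
        node_config = config
        if node.map_distances_cM is not None:
            node_config = replace(config, map_distances_cM=node.map_distances_cM)
        progeny, table = simulate_cross(
            mate_a, mate_b, node.n, panel, node_config, rng=rng, population=node.id
        )
        wild = 0.5 * (results[pa].wild_fraction + results[pb].wild_fraction)
        if (
            modifier is not NO_MODIFIER
            and modifier.carriage_scheme is CarriageScheme.GENOME_FRACTION
        ):
            prob = (
                ROLE_CARRIAGE[CarriageScheme.GENOME_FRACTION][node.role]
                if node.role is not None
                else wild
            )
            carries = rng.random(node.n) < prob
            progeny = [
                ColonyGenotype(g.id, g.haplotypes, modifier_copies=int(c))
                for g, c in zip(progeny, carries)
            ]
            table = genotype_table(progeny, panel, node.id)
        results[node.id] = SimulatedPopulation(progeny, table, wild)
    return results


# ---------------------------------------------------------------------------
# homozygote retrieval and fusion assays
# ---------------------------------------------------------------------------

def select_homozygotes(
    table: pd.DataFrame, founder: Haplotype, panel: MarkerPanel
) -> pd.DataFrame:
    """Rows homozygous for the founder's alleles at every ARC marker.

    Rows carrying a recombinant call over the interval (any marker not
    homozygous for the founder allele) are excluded, as are rows with
    missing calls — mirroring how ARC homozygotes were retrieved by
    genotyping the markers spanning the complex.
    """
    mask = pd.Series(True, index=table.index)
    for m in panel.markers:
        want = format_pair(founder.marker_alleles[m], founder.marker_alleles[m])
        mask &= table[m].astype(str) == want
    return table[mask]


def select_homozygote_genotypes(
    progeny: Sequence[ColonyGenotype], founder: Haplotype, panel: MarkerPanel
) -> list[ColonyGenotype]:
    """Genotype-object counterpart of :func:`select_homozygotes`."""
    out = []
    for g in progeny:
        if all(
            h.marker_alleles[m] == founder.marker_alleles[m]
            for h in g.haplotypes
            for m in panel.markers
        ):
            out.append(g)
    return out


def simulate_fusion_assay(
    progeny: Sequence[ColonyGenotype],
    tester: ColonyGenotype,
    model: ModifierModel,
    rng: np.random.Generator,
) -> list[FusibilityOutcome]:
    """Observed fusion-assay outcomes of each progeny against a tester colony.

    The baseline outcome comes from the alr fusion rules.  A progeny whose
    modifier genotype meets the inheritance mode expresses the modifier with
    probability ``penetrance``; expression replaces the baseline with a
    departure (rejection).  Baseline rejection cannot depart further and is
    left unchanged.
    """
    observed = []
    for g in progeny:
        outcome = classify_fusibility(g, tester)
        if model.expresses(g.modifier_copies) and rng.random() < model.penetrance:
            if outcome is not FusibilityOutcome.REJECTION:
                outcome = FusibilityOutcome.REJECTION
        observed.append(outcome)
    return observed
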