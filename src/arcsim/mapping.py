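"""Two-point and multipoint linkage analysis for ARC testcross data.

A testcross (one parent heterozygous at the scored markers, the other
homozygous) makes recombinants directly countable: the allele each progeny
inherited from the informative parent identifies which of that parent's two
haplotypes donated it, and a switch of donor between two markers is a
recombination event.  The recombination fraction MLE is then simply R/N.

Map functions convert recombination fractions to additive centimorgan
distances: Haldane assumes no crossover interference, Kosambi partial
interference.  Marker orders are ranked by the complete-data multipoint
log10 likelihood with per-interval MLE recombination fractions, and map
distances are compared across crosses with a G-test of homogeneity of
recombination fractions (the "total heterogeneity of fit" decomposition
specialized to binomial recombinant counts: G_total = G_pooled + G_het,
exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2

from .core import (
    ArcsimError,
    ColonyGenotype,
    ConfigError,
    MarkerPanel,
    MISSING,
    marker_prefix,
    parse_pair,
)

MAP_FUNCTIONS = ("haldane", "kosambi")


class PhaseError(ArcsimError):
    """Haplotype phase of the informative parent cannot be resolved."""


class DesignError(ArcsimError):
    """The data do not form a supported testcross configuration."""


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def map_function(r: float, kind: str = "haldane") -> float:
    """Map distance in cM for recombination fraction ``r`` (0 <= r < 0.5).

    Haldane: d = -50 ln(1 - 2r).  Kosambi: d = 25 ln((1 + 2r)/(1 - 2r)).
    """
    if not 0.0 <= r < 0.5:
        raise ConfigError(f"recombination fraction {r} outside [0, 0.5)")
    if kind == "haldane":
        return -50.0 * math.log1p(-2.0 * r)
    if kind == "kosambi":
        return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    raise ConfigError(f"unknown map function {kind!r}")


def inverse_map_function(d_cM: float, kind: str = "haldane") -> float:
    """Recombination fraction for map distance ``d_cM`` >= 0."""
    if d_cM < 0:
        raise ConfigError(f"negative map distance {d_cM}")
    if kind == "haldane":
        return 0.5 * -math.expm1(-d_cM / 50.0)
    if kind == "kosambi":
        e = math.exp(d_cM / 25.0)
        return (e - 1.0) / (2.0 * (e + 1.0))
    raise ConfigError(f"unknown map function {kind!r}")


# ---------------------------------------------------------------------------
# recombinant scoring
# ---------------------------------------------------------------------------

def transmitted_origins(
    table: pd.DataFrame,
    informative_parent: ColonyGenotype,
    tester: ColonyGenotype,
    markers: Sequence[str],
) -> pd.DataFrame:
    """Which haplotype of the informative parent each progeny inherited.

    Returns a frame indexed like ``table`` with one column per marker whose
    entries are 0 (first haplotype of ``informative_parent``), 1 (second) or
    NaN (missing call, or call not resolvable under the testcross model).

    The tester must be homozygous at every scored marker and the informative
    parent heterozygous (phase is given by the order of its haplotypes, which
    comes from the pedigree founders).
    """
    h0, h1 = informative_parent.haplotypes
    out = {}
    for m in markers:
        a0, a1 = h0.marker_alleles[m], h1.marker_alleles[m]
        t0, t1 = (h.marker_alleles[m] for h in tester.haplotypes)
        if t0 != t1:
            raise DesignError(f"tester heterozygous at marker {m}: not a testcross")
        if a0 == a1:
            raise PhaseError(f"informative parent homozygous at marker {m}")
        col = np.full(len(table), np.nan)
        for i, call in enumerate(table[m].astype(str)):
            pair = parse_pair(call)
            if pair is None:
                continue
            # remove one tester allele to recover the transmitted allele
            alleles = list(pair)
            if t0 not in alleles:
                raise DesignError(
                    f"call {call!r} at {m} lacks the tester allele {t0!r}"
                )
            alleles.remove(t0)
            transmitted = alleles[0]
            if transmitted == a0:
                col[i] = 0.0
            elif transmitted == a1:
                col[i] = 1.0
            else:
                raise DesignError(
                    f"transmitted allele {transmitted!r} at {m} matches neither "
                    f"haplotype of the informative parent"
                )
        out[m] = col
    return pd.DataFrame(out, index=table.index)


def score_recombinants(
    table: pd.DataFrame,
    informative_parent: ColonyGenotype,
    tester: ColonyGenotype,
    marker_a: str,
    marker_b: str,
) -> tuple[int, int]:
    """Count recombinants between two markers in a testcross table.

    Returns ``(R, N)``: N = progeny with resolvable calls at both markers,
    R = those whose transmitted alleles derive from different parental
    haplotypes of the informative parent.
    """
    org = transmitted_origins(table, informative_parent, tester, [marker_a, marker_b])
    ok = org[marker_a].notna() & org[marker_b].notna()
    n = int(ok.sum())
    r = int((org.loc[ok, marker_a] != org.loc[ok, marker_b]).sum())
    return r, n


def infer_testcross_parents(
    table: pd.DataFrame, markers: Sequence[str]
) -> tuple[ColonyGenotype, ColonyGenotype]:
    """Reconstruct (informative_parent, tester) from a testcross table.

    At every marker exactly two genotype classes must segregate; the allele
    common to both classes is the tester's (homozygous) allele and the two
    remaining alleles belong to the informative parent.  Phase is assigned
    in coupling: the tester-matching allele of the informative parent (or,
    when neither matches, the lexicographically smaller one) is placed on
    its first haplotype at every marker.  Use explicit pedigree founders
    instead whenever they are available — this inference cannot see
    repulsion-phase configurations.
    """
    from .core import Haplotype  # local: avoid re-export confusion

    h0_alleles, h1_alleles, tester_alleles = {}, {}, {}
    for m in markers:
        classes = set()
        for call in table[m].astype(str):
            pair = parse_pair(call)
            if pair is not None:
                classes.add(pair)
        if len(classes) != 2:
            raise DesignError(
                f"marker {m} shows {len(classes)} genotype classes; a "
                f"testcross segregates exactly two"
            )
        c1, c2 = sorted(classes)
        shared = set(c1) & set(c2)
        if len(shared) != 1:
            raise PhaseError(
                f"marker {m}: classes {c1}/{c2} share {len(shared)} alleles; "
                f"cannot identify the tester allele"
            )
        t = shared.pop()
        rest = []
        for c in (c1, c2):
            alleles = list(c)
            alleles.remove(t)
            rest.append(alleles[0])
        a, b = sorted(rest)
        if t in rest:
            a, b = t, (rest[0] if rest[1] == t else rest[1])
        tester_alleles[m] = t
        h0_alleles[m], h1_alleles[m] = a, b
    h0 = Haplotype("inferred-0", h0_alleles, "0", "0")
    h1 = Haplotype("inferred-1", h1_alleles, "1", "1")
    t0 = Haplotype("inferred-tester", tester_alleles, "t", "t")
    return (
        ColonyGenotype("informative", (h0, h1)),
        ColonyGenotype("tester", (t0, t0)),
    )


# ---------------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPointEstimate:
    """Testcross two-point estimate between a marker pair."""

    marker_a: str
    marker_b: str
    R: int
    N: int
    r_hat: float
    se: float
    lod: float
    d_cM: float
    map_kind: str = "haldane"


def _xlog10(x: float, y: float) -> float:
    """x * log10(y) with the 0 * log(0) = 0 convention."""
    return 0.0 if x == 0 else x * math.log10(y)


def two_point(
    R: int,
    N: int,
    map_kind: str = "haldane",
    marker_a: str = "A",
    marker_b: str = "B",
) -> TwoPointEstimate:
    """Two-point estimate from recombinant count R out of N informative progeny.

    r_hat = R/N is the testcross MLE; the LOD score is the log10 likelihood
    ratio of r_hat against free recombination (r = 0.5).  Distances for
    r_hat >= 0.5 are unbounded and reported as +inf.
    """
    if N <= 0:
        raise DesignError("no informative progeny (N = 0)")
    if not 0 <= R <= N:
        raise ConfigError(f"R = {R} outside [0, N = {N}]")
    r_hat = R / N
    se = math.sqrt(r_hat * (1.0 - r_hat) / N)
    lod = _xlog10(R, r_hat / 0.5 if r_hat > 0 else 1.0) + _xlog10(
        N - R, (1.0 - r_hat) / 0.5 if r_hat < 1 else 1.0
    )
    d = map_function(r_hat, map_kind) if r_hat < 0.5 else math.inf
    return TwoPointEstimate(marker_a, marker_b, R, N, r_hat, se, lod, d, map_kind)


# ---------------------------------------------------------------------------
# prefix-group collapsing
# ---------------------------------------------------------------------------

def collapse_prefix_groups(
    table: pd.DataFrame, panel: MarkerPanel
) -> tuple[pd.DataFrame, dict]:
    """Collapse same-prefix markers (e.g. 194m6, 194c17) to one locus each.

    Markers sharing a numeric prefix are closely linked relative to the ARC
    and are treated as identical for mapping.  An individual's collapsed call
    is the common call of its same-prefix markers; individuals whose
    same-prefix markers disagree (intra-group recombinants) are set missing
    at that locus and counted in the returned diagnostics dict.
    """
    groups: dict[str, list[str]] = {}
    for m in panel.markers:
        groups.setdefault(marker_prefix(m), []).append(m)
    meta = [c for c in table.columns if c not in panel.markers]
    out = table[meta].copy()
    diagnostics: dict[str, int] = {}
    for prefix, members in groups.items():
        calls = table[members].astype(str)
        non_missing = calls.where(calls != MISSING)
        common = non_missing.bfill(axis=1).iloc[:, 0]
        agree = non_missing.apply(
            lambda row: row.dropna().nunique() <= 1, axis=1
        )
        collapsed = common.where(agree & common.notna(), MISSING).fillna(MISSING)
        diagnostics[prefix] = int((~agree).sum())
        out[prefix] = collapsed
    return out, diagnostics


# ---------------------------------------------------------------------------
# multipoint likelihood and order search
# ---------------------------------------------------------------------------

def multipoint_loglik(
    table: pd.DataFrame,
    order: Sequence[str],
    informative_parent: ColonyGenotype,
    tester: ColonyGenotype,
    pair_counts: dict[frozenset, tuple[int, int]] | None = None,
) -> float:
    """Complete-data multipoint log10 likelihood of a marker order.

    Each adjacent interval is scored independently on pairwise-complete
    individuals with its MLE recombination fraction:
    sum_i [ R_i log10(r_i) + (N_i - R_i) log10(1 - r_i) ].
    ``pair_counts`` may supply precomputed ``(R, N)`` per marker pair.
    """
    total = 0.0
    for a, b in zip(order, order[1:]):
        if pair_counts is not None:
            R, N = pair_counts[frozenset((a, b))]
        else:
            R, N = score_recombinants(table, informative_parent, tester, a, b)
        if N == 0:
            continue
        r = R / N
        total += _xlog10(R, r if r > 0 else 1.0) + _xlog10(
            N - R, (1.0 - r) if r < 1 else 1.0
        )
    return total


@dataclass(frozen=True)
class OrderRanking:
    """Marker orders ranked by relative log10 multipoint likelihood."""

    orders: tuple[tuple[str, ...], ...]
    rel_log10_likelihood: tuple[float, ...]  # best = 0, others <= 0

    @property
    def best(self) -> tuple[str, ...]:
        return self.orders[0]

    def odds_against(self, i: int) -> float:
        """Odds ratio 10**|relative log10 likelihood| against order i."""
        return 10.0 ** (-self.rel_log10_likelihood[i])

    @property
    def ties(self) -> tuple[tuple[str, ...], ...]:
        return tuple(
            o for o, ll in zip(self.orders, self.rel_log10_likelihood) if ll == 0.0
        )


def _canonical(order: tuple[str, ...]) -> tuple[str, ...]:
    rev = order[::-1]
    return min(order, rev)


def order_search(
    table: pd.DataFrame,
    panel: MarkerPanel,
    informative_parent: ColonyGenotype,
    tester: ColonyGenotype,
    max_markers: int = 8,
) -> OrderRanking:
    """Exhaustively rank marker orders by multipoint likelihood.

    Reversal-equivalent orders are deduplicated (a map read right-to-left is
    the same map).  Limited to ``max_markers`` markers since enumeration is
    factorial.
    """
    markers = panel.markers
    if len(markers) > max_markers:
        raise DesignError(
            f"{len(markers)} markers exceed the exhaustive-search limit "
            f"({max_markers})"
        )
    pair_counts = {}
    for i, a in enumerate(markers):
        for b in markers[i + 1 :]:
            pair_counts[frozenset((a, b))] = score_recombinants(
                table, informative_parent, tester, a, b
            )
    seen = set()
    scored = []
    for perm in permutations(markers):
        canon = _canonical(perm)
        if canon in seen:
            continue
        seen.add(canon)
        ll = multipoint_loglik(
            table, canon, informative_parent, tester, pair_counts=pair_counts
        )
        scored.append((canon, ll))
    scored.sort(key=lambda t: (-t[1], t[0]))
    best_ll = scored[0][1]
    return OrderRanking(
        orders=tuple(o for o, _ in scored),
        rel_log10_likelihood=tuple(ll - best_ll for _, ll in scored),
    )


# ---------------------------------------------------------------------------
# heterogeneity of recombination fractions across crosses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeterogeneityResult:
    """G-statistic decomposition for replicated binomial recombinant counts.

    ``g_total = g_pooled + g_het`` holds exactly: the total G of all crosses
    against the r = 0.5 null splits into a pooled-fraction component and a
    between-cross heterogeneity component.  Homogeneity of recombination
    fractions is judged by ``g_het`` on ``df_het = k - 1`` degrees of freedom.
    """

    g_pooled: float
    g_het: float
    g_total: float
    df_pooled: int
    df_het: int
    p_het: float


def _g_binom(R: float, N: float, p: float) -> float:
    """2 * [R ln(R/(N p)) + (N-R) ln((N-R)/(N(1-p)))], with 0 ln 0 = 0."""
    g = 0.0
    if R > 0:
        g += R * math.log(R / (N * p))
    if N - R > 0:
        g += (N - R) * math.log((N - R) / (N * (1.0 - p)))
    return 2.0 * g


def heterogeneity_test(per_cross: Sequence[tuple[int, int]]) -> HeterogeneityResult:
    """Test homogeneity of recombination fractions across >= 2 crosses.

    Input: per-cross ``(R, N)`` recombinant counts.  g_het sums each cross's
    G against the pooled fraction and equals the 2 x k G-test of independence
    on the recombinant/parental contingency table; its upper chi-square tail
    on k - 1 df is the heterogeneity P value.
    """
    if len(per_cross) < 2:
        raise DesignError("heterogeneity test needs >= 2 crosses")
    if any(N <= 0 for _, N in per_cross):
        raise DesignError("every cross must have N > 0")
    R_t = sum(R for R, _ in per_cross)
    N_t = sum(N for _, N in per_cross)
    k = len(per_cross)
    if R_t == 0 or R_t == N_t:
        # degenerate: pooled fraction on the boundary, no heterogeneity
        g_pooled = _g_binom(R_t, N_t, 0.5)
        return HeterogeneityResult(g_pooled, 0.0, g_pooled, 1, k - 1, 1.0)
    r_pooled = R_t / N_t
    g_het = sum(_g_binom(R, N, r_pooled) for R, N in per_cross)
    g_pooled = _g_binom(R_t, N_t, 0.5)
    g_total = g_pooled + g_het
    p_het = float(_chi2.sf(g_het, k - 1))
    return HeterogeneityResult(g_pooled, g_het, g_total, 1, k - 1, p_het)
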