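"""1:1 Mendelian segregation tests per marker and cross.

In a testcross every marker should segregate into two genotype classes at a
1:1 ratio; a departure (segregation distortion) would confound linkage and
heterogeneity conclusions.  The test is the plain chi-square goodness of fit
with 1 df and no Yates continuity correction — the uncorrected statistic is
what published marker-segregation tables report (e.g. counts 266:225 give
3.42; the corrected value would be 3.26).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import chi2 as _chi2

from .core import ArcsimError, MarkerPanel, MISSING, parse_pair


class UndefinedTestError(ArcsimError):
    """Both genotype-class counts are zero: no test possible."""


class EncodingError(ArcsimError):
    """Genotype-class labels are inconsistent across pooled tables."""


@dataclass(frozen=True)
class SegTestResult:
    """Chi-square test of a 1:1 genotype-class split at one marker."""

    marker: str
    cross: str
    n1: int
    n2: int
    chi2: float
    p: float

    @property
    def N(self) -> int:
        return self.n1 + self.n2


def chisq_1to1(n1: int, n2: int, marker: str = "", cross: str = "") -> SegTestResult:
    """Chi-square goodness of fit of counts ``(n1, n2)`` against 1:1.

    chi2 = (n1 - N/2)^2/(N/2) + (n2 - N/2)^2/(N/2), no continuity
    correction; P is the upper chi-square tail at 1 df.
    """
    if n1 < 0 or n2 < 0:
        raise ArcsimError("counts must be non-negative")
    N = n1 + n2
    if N == 0:
        raise UndefinedTestError("both genotype-class counts are zero")
    e = N / 2.0
    chi2 = (n1 - e) ** 2 / e + (n2 - e) ** 2 / e
    return SegTestResult(marker, cross, n1, n2, chi2, float(_chi2.sf(chi2, 1)))


def genotype_class_counts(
    table: pd.DataFrame, marker: str
) -> dict[tuple[str, str], int]:
    """Count occurrences of each non-missing allele-pair class at a marker."""
    counts: dict[tuple[str, str], int] = {}
    for call in table[marker].astype(str):
        pair = parse_pair(call)
        if pair is None:
            continue
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def pool_counts(
    tables: Sequence[pd.DataFrame], marker: str
) -> tuple[int, int, tuple[str, str]]:
    """Pool two-class genotype counts for a marker across tables.

    Larval and colony samples of the same cross are pooled by elementwise
    summation; missing genotypes are excluded from both classes.  Returns
    ``(n1, n2, class_labels)`` with classes in sorted encoding order.
    Raises :class:`EncodingError` if the tables disagree on the class set or
    more than two classes appear (not a testcross marker).
    """
    pooled: dict[tuple[str, str], int] = {}
    classes: set[tuple[str, str]] | None = None
    for t in tables:
        counts = genotype_class_counts(t, marker)
        if counts:
            if classes is None:
                classes = set(counts)
            elif not set(counts) <= classes and not classes <= set(counts):
                raise EncodingError(
                    f"inconsistent genotype classes for {marker}: "
                    f"{sorted(classes)} vs {sorted(counts)}"
                )
            classes |= set(counts)
        for k, v in counts.items():
            pooled[k] = pooled.get(k, 0) + v
    if not pooled:
        return 0, 0, ("", "")
    if len(pooled) > 2:
        raise EncodingError(
            f"{marker} has {len(pooled)} genotype classes; 1:1 test needs two"
        )
    # homozygous class first (the layout segregation tables print), then
    # lexicographic
    keys = sorted(pooled, key=lambda k: (k[0] != k[1], k))
    if len(keys) == 1:
        keys.append(("", ""))
        pooled[("", "")] = 0
    labels = tuple("/".join(k) for k in keys)
    return pooled[keys[0]], pooled[keys[1]], labels  # type: ignore[return-value]


def segregation_report(
    crosses: Mapping[str, Sequence[pd.DataFrame]], panel: MarkerPanel
) -> pd.DataFrame:
    """Marker-segregation table: one row per (cross, marker).

    Columns: cross, marker, the two genotype-class labels with their counts,
    N, chi2 and P.  This doubles as a segregation-distortion scan: distorted
    markers show small P.  Markers absent from a cross's tables (all calls
    missing) are skipped.
    """
    rows = []
    for cross_id, tables in crosses.items():
        for m in panel.markers:
            if not any(m in t.columns for t in tables):
                continue
            present = [t for t in tables if m in t.columns]
            n1, n2, labels = pool_counts(present, m)
            if n1 + n2 == 0:
                continue
            res = chisq_1to1(n1, n2, marker=m, cross=cross_id)
            rows.append(
                {
                    "cross": cross_id,
                    "marker": m,
                    "class1": labels[0],
                    "n1": n1,
                    "class2": labels[1],
                    "n2": n2,
                    "N": res.N,
                    "chi2": res.chi2,
                    "P": res.p,
                }
            )
    return pd.DataFrame(
        rows, columns=["cross", "marker", "class1", "n1", "class2", "n2", "N", "chi2", "P"]
    )
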