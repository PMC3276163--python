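"""Tables, reports, configs and the named pedigree presets.

Genotype tables travel as TSV (UTF-8, Unix newlines, tab-separated so
allele symbols never need quoting): one row per individual, columns
``individual``, optional ``population``, one column per marker holding an
``x/y`` allele-pair call (``-`` = missing), and an optional ``modifier``
column with the unlinked-modifier copy number.  Pairs are unordered and are
normalized lexicographically on read.

Presets mirror the published breeding designs: three wild-type outcross
pedigrees (OQ6D with haplotypes c/d, LH06-082 with a/b, LH06-003 with
i/r2, each crossed into the near-inbred ARC-f/f or ARC-r/r lines) and the
congenic f/r testcross.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    ArcsimError,
    ColonyGenotype,
    Haplotype,
    MarkerPanel,
    MISSING,
    format_pair,
    founder_haplotype,
    parse_pair,
)
from .simulate import PedigreeNode, PedigreeSpec, SimulationConfig

META_COLUMNS = ("individual", "population", "modifier")


class ParseError(ArcsimError):
    """A genotype table failed validation."""


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV genotype table.

    Allele pairs are normalized (``d/f`` == ``f/d``); ``-`` stays as the
    missing sentinel.  Raises :class:`ParseError` with the offending line
    number on malformed pairs or duplicate individual ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
    if "individual" not in df.columns:
        raise ParseError(f"{path}: missing required column 'individual'")
    dupes = df["individual"][df["individual"].duplicated()]
    if len(dupes):
        raise ParseError(f"{path}: duplicated individual id {dupes.iloc[0]!r}")
    marker_cols = [c for c in df.columns if c not in META_COLUMNS]
    for col in marker_cols:
        normalized = []
        for i, raw in enumerate(df[col]):
            try:
                pair = parse_pair(raw)
            except ArcsimError as e:
                # +2: header line plus 1-based numbering
                raise ParseError(f"{path}:{i + 2}: column {col}: {e}") from None
            normalized.append(MISSING if pair is None else format_pair(*pair))
        df[col] = normalized
    return df


def write_genotype_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a genotype table as TSV with Unix newlines."""
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def format_segregation_text(report: pd.DataFrame) -> str:
    """Human-readable marker-segregation table.

    chi-square to 2-4 significant figures and P to 2, mirroring how marker
    segregation ratios are conventionally printed.
    """
    lines = [
        f"{'Cross':<14}{'Marker':<10}{'Class 1':>10}{'n1':>6}"
        f"{'Class 2':>10}{'n2':>6}{'N':>6}{'chi2':>9}{'P':>8}"
    ]
    for _, row in report.iterrows():
        lines.append(
            f"{row['cross']:<14}{row['marker']:<10}{row['class1']:>10}"
            f"{row['n1']:>6}{row['class2']:>10}{row['n2']:>6}{row['N']:>6}"
            f"{row['chi2']:>9.4g}{row['P']:>8.2g}"
        )
    return "\n".join(lines) + "\n"


def format_order_ranking(ranking) -> str:
    """Order-ranking report: relative log10 likelihood and odds per order."""
    lines = [f"{'Order':<40}{'rel log10 L':>12}{'odds against':>14}"]
    for order, rel in zip(ranking.orders, ranking.rel_log10_likelihood):
        odds = 10.0 ** (-rel)
        lines.append(f"{'-'.join(order):<40}{rel:>12.2f}{odds:>13.4g}:1")
    return "\n".join(lines) + "\n"


def format_map_text(
    estimates: Sequence, title: str = "linkage map"
) -> str:
    """Per-interval map table plus a to-scale text rendering (1 char ~ 1 cM)."""
    lines = [title, f"{'Interval':<22}{'R':>5}{'N':>6}{'r_hat':>8}{'SE':>8}{'LOD':>8}{'cM':>7}"]
    for e in estimates:
        lines.append(
            f"{e.marker_a + '-' + e.marker_b:<22}{e.R:>5}{e.N:>6}"
            f"{e.r_hat:>8.4f}{e.se:>8.4f}{e.lod:>8.2f}{e.d_cM:>7.1f}"
        )
    total = sum(e.d_cM for e in estimates)
    scale = ""
    for e in estimates:
        scale += e.marker_a + "|" + "-" * max(1, round(e.d_cM))
    if estimates:
        scale += estimates[-1].marker_b + "|"
        lines.append(scale)
    lines.append(f"total: {total:.1f} cM")
    return "\n".join(lines) + "\n"


def write_reports(results: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write analysis results deterministically under ``out_dir``.

    Recognized keys: ``segregation`` (DataFrame), ``map`` (list of
    TwoPointEstimate), ``order`` (OrderRanking), ``heterogeneity``
    (HeterogeneityResult), ``power`` (PowerResult).  Each becomes a TSV
    and/or plain-text file; the paths written are returned.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, text: str) -> None:
        p = out_dir / name
        p.write_text(text, encoding="utf-8", newline="\n")
        written.append(p)

    if "segregation" in results:
        rep: pd.DataFrame = results["segregation"]  # type: ignore[assignment]
        _write("segregation.tsv", rep.to_csv(sep="\t", index=False, lineterminator="\n"))
        _write("segregation.txt", format_segregation_text(rep))
    if "map" in results:
        ests = results["map"]
        rows = pd.DataFrame(
            [
                {
                    "marker_a": e.marker_a,
                    "marker_b": e.marker_b,
                    "R": e.R,
                    "N": e.N,
                    "r_hat": round(e.r_hat, 6),
                    "se": round(e.se, 6),
                    "lod": round(e.lod, 2),
                    "d_cM": round(e.d_cM, 1),
                }
                for e in ests
            ]
        )
        _write("map.tsv", rows.to_csv(sep="\t", index=False, lineterminator="\n"))
        _write("map.txt", format_map_text(ests))
    if "order" in results:
        _write("order.txt", format_order_ranking(results["order"]))
    if "heterogeneity" in results:
        h = results["heterogeneity"]
        _write(
            "heterogeneity.txt",
            (
                f"g_pooled\t{h.g_pooled:.4f}\t(df={h.df_pooled})\n"
                f"g_het\t{h.g_het:.4f}\t(df={h.df_het})\n"
                f"g_total\t{h.g_total:.4f}\n"
                f"p_het\t{h.p_het:.4g}\n"
            ),
        )
    if "power" in results:
        p = results["power"]
        _write(
            "power.txt",
            (
                f"p_miss\t{p.p_miss:.6g}\n"
                f"detect_power\t{p.detect_power:.6g}\n"
                f"reject_null\t{p.reject_null}\n"
            ),
        )
    return written


# ---------------------------------------------------------------------------
# founder haplotypes from JSON
# ---------------------------------------------------------------------------

def founders_from_json(config: str | Mapping) -> dict[str, Haplotype]:
    """Parse founder haplotype definitions from a JSON config block.

    Format: ``{"founders": [{"label": "f", "marker_alleles": {...},
    "alr1": "f", "alr2": "f"}, ...]}``.
    """
    if isinstance(config, str):
        config = json.loads(config)
    out = {}
    for entry in config["founders"]:
        h = Haplotype(
            label=entry["label"],
            marker_alleles=entry["marker_alleles"],
            alr1_allele=entry["alr1"],
            alr2_allele=entry["alr2"],
        )
        out[h.label] = h
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

DEFAULT_MARKERS = ("194m6", "18m1", "28m6", "174m4")
# fraction of the total 194->174 distance per adjacent interval
INTERVAL_FRACTIONS = (0.4, 0.2, 0.4)

CONGENIC_TOTAL_CM = 1.6
WILD_TOTALS_CM = {"d": 30.5, "c": 19.8}  # Fig-3-style wild haplotype totals

PRESET_NAMES = ("OQ6D", "LH06-082", "LH06-003", "congenic-fr")


def split_total(total_cM: float, fractions: Sequence[float] = INTERVAL_FRACTIONS) -> tuple[float, ...]:
    return tuple(total_cM * f for f in fractions)


@dataclass(frozen=True)
class Preset:
    """A named breeding design ready for :func:`arcsim.simulate.simulate_pedigree`."""

    name: str
    panel: MarkerPanel
    founders: dict[str, Haplotype]
    spec: PedigreeSpec
    map_distances_cM: tuple[float, ...]
    wild_founders: frozenset[str]
    analysis_populations: tuple[str, ...]
    target_label: str  # inbred haplotype whose homozygotes get assayed
    tester: ColonyGenotype

    def config(self, seed: int, map_function: str = "haldane") -> SimulationConfig:
        return SimulationConfig(seed, self.map_distances_cM, map_function)


def _pair(f: dict[str, Haplotype], a: str, b: str, id: str) -> ColonyGenotype:
    return ColonyGenotype(id, (f[a], f[b]))


def load_preset(name: str, n_scale: float = 1.0) -> Preset:
    """Build a named pedigree preset.

    ``n_scale`` multiplies every analysis-population progeny count, so small
    test runs and full-size runs share one topology.  Unknown names raise
    with the list of available presets.
    """
    panel = MarkerPanel(DEFAULT_MARKERS)

    def N(n: int) -> int:
        return max(1, round(n * n_scale))

    if name == "congenic-fr":
        founders = {lbl: founder_haplotype(lbl, panel) for lbl in ("f", "r")}
        spec = PedigreeSpec(
            (
                PedigreeNode("inbred_f", founder=_pair(founders, "f", "f", "inbred_f")),
                PedigreeNode("congenic_fr", founder=_pair(founders, "f", "r", "congenic_fr")),
                PedigreeNode(
                    "MP", parents=("inbred_f", "congenic_fr"), n=N(590),
                    role="backcross_progeny",
                ),
            )
        )
        return Preset(
            name, panel, founders, spec, split_total(CONGENIC_TOTAL_CM),
            frozenset(), ("MP",), "f",
            tester=_pair(founders, "f", "f", "tester_ff"),
        )

    if name == "OQ6D":
        founders = {lbl: founder_haplotype(lbl, panel) for lbl in ("f", "c", "d")}
        d_fd = split_total(WILD_TOTALS_CM["d"])
        d_fc = split_total(WILD_TOTALS_CM["c"])
        spec = PedigreeSpec(
            (
                PedigreeNode("inbred_f", founder=_pair(founders, "f", "f", "inbred_f")),
                PedigreeNode("OQ6D", founder=_pair(founders, "c", "d", "OQ6D")),
                PedigreeNode("F1", parents=("inbred_f", "OQ6D"), n=24),
                PedigreeNode(
                    "AP110", parents=("inbred_f", "F1"),
                    parent_labels=(None, frozenset({"f", "d"})), n=N(295),
                    role="backcross_progeny", map_distances_cM=d_fd,
                ),
                PedigreeNode(
                    "AP111", parents=("inbred_f", "F1"),
                    parent_labels=(None, frozenset({"f", "d"})), n=N(295),
                    role="backcross_progeny", map_distances_cM=d_fd,
                ),
                PedigreeNode(
                    "AP105", parents=("inbred_f", "F1"),
                    parent_labels=(None, frozenset({"f", "c"})), n=N(285),
                    role="backcross_progeny", map_distances_cM=d_fc,
                ),
                PedigreeNode(
                    "LB132", parents=("inbred_f", "F1"),
                    parent_labels=(None, frozenset({"f", "c"})), n=N(70),
                    role="backcross_progeny", map_distances_cM=d_fc,
                ),
            )
        )
        return Preset(
            name, panel, founders, spec, d_fd, frozenset({"OQ6D"}),
            ("AP110", "AP111", "AP105", "LB132"), "f",
            tester=_pair(founders, "f", "f", "tester_ff"),
        )

    if name == "LH06-082":
        founders = {lbl: founder_haplotype(lbl, panel) for lbl in ("r", "a", "b")}
        spec = PedigreeSpec(
            (
                PedigreeNode("inbred_r", founder=_pair(founders, "r", "r", "inbred_r")),
                PedigreeNode("LH06-082", founder=_pair(founders, "a", "b", "LH06-082")),
                PedigreeNode("F1", parents=("inbred_r", "LH06-082"), n=24),
                PedigreeNode(
                    "F2", parents=("F1", "F1"),
                    parent_labels=(frozenset({"r", "a"}), frozenset({"r", "b"})),
                    n=N(44), role="f2_incross_progeny",
                ),
            )
        )
        return Preset(
            name, panel, founders, spec, split_total(WILD_TOTALS_CM["c"]),
            frozenset({"LH06-082"}), ("F2",), "r",
            tester=_pair(founders, "r", "r", "tester_rr"),
        )

    if name == "LH06-003":
        founders = {lbl: founder_haplotype(lbl, panel) for lbl in ("f", "i", "r2")}
        spec = PedigreeSpec(
            (
                PedigreeNode("inbred_f", founder=_pair(founders, "f", "f", "inbred_f")),
                PedigreeNode("LH06-003", founder=_pair(founders, "i", "r2", "LH06-003")),
                PedigreeNode("F1", parents=("inbred_f", "LH06-003"), n=24),
                PedigreeNode(
                    "F2", parents=("F1", "F1"),
                    parent_labels=(frozenset({"f", "i"}), frozenset({"f", "r2"})),
                    n=N(30), role="f2_incross_progeny",
                ),
                PedigreeNode(
                    "T1", parents=("F2", "inbred_f"),
                    parent_labels=(frozenset({"f", "i"}), None),
                    n=N(30), role="terminal_25pct",
                ),
                PedigreeNode(
                    "T2", parents=("F2", "inbred_f"),
                    parent_labels=(frozenset({"f", "r2"}), None),
                    n=N(30), role="terminal_25pct",
                ),
            )
        )
        return Preset(
            name, panel, founders, spec, split_total(WILD_TOTALS_CM["c"]),
            frozenset({"LH06-003"}), ("F2", "T1", "T2"), "f",
            tester=_pair(founders, "f", "f", "tester_ff"),
        )

    raise ArcsimError(
        f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
    )
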