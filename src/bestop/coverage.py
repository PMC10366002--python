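"""Targeting-space and genomic-coverage statistics across PAM variants.

For a genome and a PAM, the *targeting space* is the number of qualifying
STOP-capable protospacers in the first 75% of their CDS, and the *genomic
coverage* is the percentage of (non-pseudo) CDSs with at least one such
protospacer. Reports aggregate these across PAM variants and unions of them,
which is how base editors with relaxed PAMs (NG, NAA) are compared against
the canonical NGG editor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Literal, Sequence

import pandas as pd

from .design import EditingWindow, PamSpec, ProtospacerHit, design_knockouts
from .genome import AnnotatedGenome, extract_cds_records

__all__ = [
    "CoverageReport",
    "Convention",
    "targeting_space",
    "genomic_coverage",
    "combined_coverage",
    "pam_comparison_report",
    "find_matching_convention",
]

CountingMode = Literal["pair", "site"]


def _count_hits(hits: Sequence[ProtospacerHit], counting: CountingMode) -> int:
    if counting == "pair":
        return len(hits)
    if counting == "site":
        return len({(h.genome_start, h.protospacer_strand) for h in hits})
    raise ValueError(f"unknown counting mode {counting!r}")


def _covered_ids(hits: Sequence[ProtospacerHit]) -> set[str]:
    return {h.cds_id for h in hits}


def _design(genome, pam, window, first_fraction, anchor, single_only):
    return design_knockouts(
        genome, pam, window, first_fraction, anchor=anchor, single_only=single_only
    )


def targeting_space(
    genome: AnnotatedGenome,
    pam: PamSpec,
    window: EditingWindow = EditingWindow(),
    first_fraction: float = 0.75,
    *,
    counting: CountingMode = "pair",
    anchor: str = "stop",
    single_only: bool = False,
) -> int:
    """Number of qualifying STOP-capable protospacers genome-wide."""
    hits = _design(genome, pam, window, first_fraction, anchor, single_only)
    return _count_hits(hits, counting)


def genomic_coverage(
    genome: AnnotatedGenome,
    pam: PamSpec,
    window: EditingWindow = EditingWindow(),
    first_fraction: float = 0.75,
    *,
    anchor: str = "stop",
    single_only: bool = False,
) -> float:
    """Percentage of non-pseudo CDSs with >= 1 qualifying protospacer."""
    total = len(extract_cds_records(genome))
    if total == 0:
        raise ValueError("genome has no non-pseudo CDS")
    hits = _design(genome, pam, window, first_fraction, anchor, single_only)
    return 100.0 * len(_covered_ids(hits)) / total


def combined_coverage(
    genome: AnnotatedGenome,
    pam_set: Iterable[PamSpec],
    window: EditingWindow = EditingWindow(),
    first_fraction: float = 0.75,
    *,
    anchor: str = "stop",
    single_only: bool = False,
) -> float:
    """Coverage of the union of covered-CDS sets across several PAMs."""
    pam_set = list(pam_set)
    if not pam_set:
        raise ValueError("pam_set must be non-empty")
    total = len(extract_cds_records(genome))
    if total == 0:
        raise ValueError("genome has no non-pseudo CDS")
    covered: set[str] = set()
    for pam in pam_set:
        covered |= _covered_ids(_design(genome, pam, window, first_fraction,
                                        anchor, single_only))
    return 100.0 * len(covered) / total


@dataclass
class CoverageReport:
    """Per-PAM and union targeting-space/coverage table plus its parameters."""

    table: pd.DataFrame
    window: EditingWindow
    first_fraction: float
    counting: str
    anchor: str
    single_only: bool

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.2f")

    def row(self, name: str) -> pd.Series:
        sub = self.table[self.table["pam"] == name]
        if sub.empty:
            raise KeyError(name)
        return sub.iloc[0]

    def plot(self, path: str) -> None:
        """Bar chart of targeting space and coverage per PAM."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].bar(self.table["pam"], self.table["targeting_space"], color="#4878b0")
        axes[0].set_ylabel("STOP-capable protospacers")
        axes[1].bar(self.table["pam"], self.table["coverage_pct"], color="#b04848")
        axes[1].set_ylabel("genomic coverage (%)")
        axes[1].set_ylim(0, 100)
        for ax in axes:
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def pam_comparison_report(
    genome: AnnotatedGenome,
    pam_list: Sequence[PamSpec],
    window: EditingWindow = EditingWindow(),
    first_fraction: float = 0.75,
    *,
    unions: Sequence[Sequence[str]] = (),
    counting: CountingMode = "pair",
    anchor: str = "stop",
    single_only: bool = False,
) -> CoverageReport:
    """One row per PAM plus one per requested union of PAM names."""
    total = len(extract_cds_records(genome))
    per_pam: dict[str, tuple[int, set[str]]] = {}
    rows = []
    for pam in pam_list:
        hits = _design(genome, pam, window, first_fraction, anchor, single_only)
        covered = _covered_ids(hits)
        per_pam[pam.name] = (_count_hits(hits, counting), covered)
        rows.append({
            "pam": pam.name,
            "pattern": pam.pattern,
            "targeting_space": per_pam[pam.name][0],
            "covered_cds": len(covered),
            "total_cds": total,
            "coverage_pct": round(100.0 * len(covered) / total, 2) if total else 0.0,
        })
    for members in unions:
        covered: set[str] = set()
        space = 0
        for name in members:
            space += per_pam[name][0]
            covered |= per_pam[name][1]
        rows.append({
            "pam": "+".join(members),
            "pattern": "union",
            "targeting_space": space,
            "covered_cds": len(covered),
            "total_cds": total,
            "coverage_pct": round(100.0 * len(covered) / total, 2) if total else 0.0,
        })
    table = pd.DataFrame(rows)
    return CoverageReport(table, window, first_fraction, counting, anchor, single_only)


# ---------------------------------------------------------------------------
# convention grid


@dataclass(frozen=True)
class Convention:
    """One point of the counting-convention grid."""

    window: EditingWindow = EditingWindow(-19, -16)
    anchor: str = "stop"
    counting: str = "pair"
    single_only: bool = False

    def label(self) -> str:
        return (
            f"window={self.window.from_pos}..{self.window.to_pos},"
            f"anchor={self.anchor},counting={self.counting},"
            f"subset={'single' if self.single_only else 'any'}"
        )


DEFAULT_GRID = tuple(
    Convention(w, a, c, s)
    for w, a, c, s in product(
        (EditingWindow(-19, -16), EditingWindow(-20, -16)),
        ("stop", "protospacer"),
        ("pair", "site"),
        (False, True),
    )
)


@dataclass
class GridResult:
    convention: Convention
    values: dict[str, float]
    matches: bool
    mismatched: list[str] = field(default_factory=list)


def find_matching_convention(
    genome: AnnotatedGenome,
    targets: dict[str, dict[str, float]],
    pam_specs: dict[str, PamSpec],
    *,
    grid: Sequence[Convention] = DEFAULT_GRID,
    first_fraction: float = 0.75,
    count_tol: int = 0,
    pct_tol: float = 0.005,
) -> list[GridResult]:
    """Run the convention grid and flag configurations reproducing ``targets``.

    ``targets`` maps a PAM name (or 'name1+name2' for a union) to
    ``{"targeting_space": int}`` and/or ``{"coverage_pct": float}`` entries.
    Returns one result per grid point, matching ones first.
    """
    results = []
    for conv in grid:
        unions = [t.split("+") for t in targets if "+" in t]
        report = pam_comparison_report(
            genome,
            [pam_specs[name] for name in pam_specs],
            conv.window,
            first_fraction,
            unions=unions,
            counting=conv.counting,
            anchor=conv.anchor,
            single_only=conv.single_only,
        )
        values: dict[str, float] = {}
        mism: list[str] = []
        for name, wanted in targets.items():
            row = report.row(name)
            for key, target in wanted.items():
                got = float(row[key])
                values[f"{name}.{key}"] = got
                tol = pct_tol if key == "coverage_pct" else count_tol
                if abs(got - float(target)) > tol:
                    mism.append(f"{name}.{key}: got {got}, want {target}")
        results.append(GridResult(conv, values, not mism, mism))
    results.sort(key=lambda r: (not r.matches, len(r.mismatched)))
    return results
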