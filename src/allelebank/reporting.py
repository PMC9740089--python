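"""The five-section result file and the summary indicators.

The report mirrors the output a hatchery manager reads after a selection
run, in five sections: (1) the input genotypes, (2) the alleles detected
across all samples, (3) the selected samples with their genotypes, (4) the
alleles those samples transfer, and (5) summary indicators: N (samples in
the input), nA (alleles detected), nA/N, N' (samples selected), N'/N in %,
and the achieved coverage.  Written as UTF-8 CSV so any spreadsheet opens
it; an XLSX mirror is available for convenience.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from ._rounding import fmt2, ratio2
from .diversity import (
    AlleleInventory,
    AllelePair,
    allele_inventory,
    sort_alleles,
)
from .genotype_io import GenotypeTable, table_rows
from .selection import SelectionResult

__all__ = [
    "SummaryStats",
    "summarize",
    "write_report",
    "report_rows",
    "SECTION_HEADERS",
]

#: Fixed one-cell header line opening each report section, in order.
SECTION_HEADERS: tuple[str, ...] = (
    "(1) Genotypes from the input file",
    "(2) Alleles detected across all samples",
    "(3) Samples selected for the transfer",
    "(4) Alleles transferred by the selected samples",
    "(5) Summary",
)


@dataclass(frozen=True)
class SummaryStats:
    """The five summary indicators plus the achieved coverage.

    ``nA_per_N`` and ``N_prime_over_N_percent`` are half-up rounded to
    2 dp, matching how the indicators are conventionally printed.
    """

    N: int
    nA: int
    nA_per_N: float
    N_prime: int
    N_prime_over_N_percent: float
    achieved_percent: float


def summarize(table: GenotypeTable, result: SelectionResult) -> SummaryStats:
    """Compute N, nA, nA/N, N', N'/N (%) and achieved coverage for a run."""
    n = table.n_samples
    n_a = allele_inventory(table).total_nA
    n_prime = len(result.selected_ids)
    return SummaryStats(
        N=n,
        nA=n_a,
        nA_per_N=ratio2(n_a, n) if n else 0.0,
        N_prime=n_prime,
        N_prime_over_N_percent=ratio2(n_prime, n, scale=100) if n else 0.0,
        achieved_percent=result.achieved_percent,
    )


# --------------------------------------------------------------------------
# Report assembly


def _allele_block(
    inventory: AlleleInventory, pairs: frozenset[AllelePair] | None = None
) -> list[list[str]]:
    """Alleles per locus as columns, with per-locus counts and the total.

    Row 1: locus names; following rows: the allele lists; last row: number
    of alleles at each locus and, in the final column, across all loci.
    Restricted to ``pairs`` when given (the transferred-allele section).
    """
    per_locus: dict[str, list[str]] = {}
    for name in inventory.locus_order:
        alleles = inventory.per_locus[name]
        if pairs is not None:
            alleles = frozenset(a for a in alleles if (name, a) in pairs)
        per_locus[name] = sort_alleles(alleles)
    depth = max((len(v) for v in per_locus.values()), default=0)
    rows = [["Locus"] + list(inventory.locus_order) + [""]]
    for i in range(depth):
        rows.append(
            [f"Allele {i + 1}"]
            + [
                per_locus[name][i] if i < len(per_locus[name]) else ""
                for name in inventory.locus_order
            ]
            + [""]
        )
    counts = [len(per_locus[name]) for name in inventory.locus_order]
    rows.append(
        ["Number of alleles"] + [str(c) for c in counts] + [str(sum(counts))]
    )
    return rows


def _selected_rows(table: GenotypeTable, result: SelectionResult) -> list[list[str]]:
    by_id = {p.sample_id: p for p in table.samples}
    selected = GenotypeTable(
        loci=table.loci,
        samples=tuple(by_id[sid] for sid in result.selected_ids),
    )
    return table_rows(selected)


def report_rows(
    table: GenotypeTable,
    inventory: AlleleInventory,
    result: SelectionResult,
    stats: SummaryStats,
) -> list[list[str]]:
    """All report cells as rows, sections separated by blank rows."""
    rows: list[list[str]] = []

    rows.append([SECTION_HEADERS[0]])
    rows.extend(table_rows(table))
    rows.append([])

    rows.append([SECTION_HEADERS[1]])
    rows.extend(_allele_block(inventory))
    rows.append([])

    rows.append([SECTION_HEADERS[2]])
    rows.extend(_selected_rows(table, result))
    rows.append([])

    rows.append([SECTION_HEADERS[3]])
    rows.extend(_allele_block(inventory, result.covered))
    rows.append([])

    rows.append([SECTION_HEADERS[4]])
    rows.extend(
        [
            ["Number of samples in the input file (N)", str(stats.N)],
            ["Number of alleles detected (nA)", str(stats.nA)],
            ["Alleles per sample (nA/N)", fmt2(stats.nA_per_N)],
            ["Number of samples selected (N')", str(stats.N_prime)],
            ["Share of samples selected (N'/N, %)",
             fmt2(stats.N_prime_over_N_percent)],
            ["Achieved coverage (%)", fmt2(stats.achieved_percent)],
            ["Solver", result.solver],
            ["Optimal", "yes" if result.optimal else "no"],
        ]
    )
    return rows


def write_report(
    table: GenotypeTable,
    inventory: AlleleInventory,
    result: SelectionResult,
    stats: SummaryStats,
    path: Union[str, Path, io.TextIOBase],
    *,
    fmt: str = "csv",
    delimiter: str = ",",
) -> None:
    """Write the five-section report to ``path`` as CSV (default) or XLSX."""
    rows = report_rows(table, inventory, result, stats)
    if fmt == "csv":
        if isinstance(path, (str, Path)):
            with open(path, "w", encoding="utf-8", newline="") as fh:
                csv.writer(fh, delimiter=delimiter, lineterminator="\n").writerows(rows)
        else:
            csv.writer(path, delimiter=delimiter, lineterminator="\n").writerows(rows)
    elif fmt == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "Report"
        for row in rows:
            ws.append(row if row else [None])
        wb.save(path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
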