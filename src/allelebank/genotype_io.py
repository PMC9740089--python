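"""Reading and writing delimited microsatellite genotype tables.

The dialect mirrors the spreadsheet layout used for gamete-bank genotype
input: column 1 holds the sample (fish) ID, and each subsequent block of
columns holds one locus — two columns for a disomic locus, four for a
tetrasomic one.  The header row carries the locus name over its block,
either repeated on every column of the block or written once with blank
cells filling the rest; ploidy is inferred from the block width.  Allele
calls are numeric labels (fragment lengths); ``0`` or an empty cell means
a missing call.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "LocusDef",
    "SampleProfile",
    "GenotypeTable",
    "GenotypeTableError",
    "StructuralError",
    "ValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "DEFAULT_MISSING_CODES",
]

#: Cell values interpreted as "no call" on input.  "0" is the de-facto
#: microsatellite missing-data convention; blank cells count as well.
DEFAULT_MISSING_CODES: tuple[str, ...] = ("0", "")

#: Missing calls are written back with this code.
DEFAULT_MISSING_OUTPUT = "0"

ALLOWED_PLOIDIES = (2, 4)

Call = Optional[str]  # allele label, or None for a missing call


class GenotypeTableError(ValueError):
    """Base class for genotype-table format and content errors."""


class StructuralError(GenotypeTableError):
    """The table's shape (header blocks, column counts) is malformed."""


class ValidationError(GenotypeTableError):
    """The table's shape is fine but a value violates the dialect."""


@dataclass(frozen=True)
class LocusDef:
    """One locus: its name, copy number, and source-column range.

    ``column_span`` is the 1-based inclusive (first, last) column range the
    locus occupies in the source table (column 1 is the sample ID).
    """

    name: str
    ploidy: int
    column_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.ploidy not in ALLOWED_PLOIDIES:
            raise StructuralError(
                f"locus {self.name!r}: ploidy must be 2 (disomic) or 4 "
                f"(tetrasomic), got {self.ploidy}"
            )
        lo, hi = self.column_span
        if hi - lo + 1 != self.ploidy:
            raise StructuralError(
                f"locus {self.name!r}: column span {self.column_span} width "
                f"{hi - lo + 1} does not match ploidy {self.ploidy}"
            )


@dataclass(frozen=True)
class SampleProfile:
    """One sample's calls: locus name -> ordered allele labels (None = missing)."""

    sample_id: str
    calls: dict[str, tuple[Call, ...]] = field(default_factory=dict)

    def __hash__(self) -> int:  # calls is a dict; hash by identity-free content
        return hash((self.sample_id, tuple(sorted(self.calls.items()))))


@dataclass(frozen=True)
class GenotypeTable:
    """Ordered loci x ordered samples, as parsed from one input file."""

    loci: tuple[LocusDef, ...]
    samples: tuple[SampleProfile, ...]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(locus.name for locus in self.loci)

    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    def validate(self) -> None:
        """Check the structural invariants; raise on violation."""
        names = self.locus_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate locus name(s): {dupes}")
        ids = self.sample_ids()
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ID(s): {dupes}")
        ploidy_of = {locus.name: locus.ploidy for locus in self.loci}
        for profile in self.samples:
            if set(profile.calls) != set(names):
                raise ValidationError(
                    f"sample {profile.sample_id!r}: calls cover loci "
                    f"{sorted(profile.calls)} but table declares {sorted(names)}"
                )
            for locus_name, calls in profile.calls.items():
                if len(calls) != ploidy_of[locus_name]:
                    raise ValidationError(
                        f"sample {profile.sample_id!r}, locus {locus_name!r}: "
                        f"{len(calls)} call slots, expected "
                        f"{ploidy_of[locus_name]}"
                    )


# --------------------------------------------------------------------------
# Parsing


def _parse_header(cells: Sequence[str]) -> tuple[LocusDef, ...]:
    """Group allele columns into loci by run length of the header names.

    Accepts both header conventions: the locus name repeated on each of its
    columns, and the name on the first column with blanks following.
    """
    if not cells:
        raise StructuralError("empty header row")
    allele_cells = [c.strip() for c in cells[1:]]
    groups: list[tuple[str, int, int]] = []  # (name, first_col, last_col)
    for offset, cell in enumerate(allele_cells):
        col = offset + 2  # 1-based source column
        if cell == "":
            if not groups:
                raise StructuralError(
                    f"column {col}: blank header cell with no locus name before it"
                )
            name, first, _ = groups[-1]
            groups[-1] = (name, first, col)
        elif groups and groups[-1][0] == cell:
            name, first, _ = groups[-1]
            groups[-1] = (name, first, col)
        else:
            groups.append((cell, col, col))
    loci = []
    for name, first, last in groups:
        width = last - first + 1
        if width not in ALLOWED_PLOIDIES:
            raise StructuralError(
                f"locus {name!r} starting at column {first}: block spans "
                f"{width} column(s), expected 2 or 4"
            )
        loci.append(LocusDef(name=name, ploidy=width, column_span=(first, last)))
    return tuple(loci)


def _parse_row(
    row_number: int,
    cells: Sequence[str],
    loci: Sequence[LocusDef],
    n_allele_columns: int,
    missing_codes: frozenset[str],
) -> SampleProfile:
    sample_id = cells[0].strip() if cells else ""
    if sample_id == "":
        raise ValidationError(f"row {row_number}: empty sample ID")
    allele_cells = [c.strip() for c in cells[1:]]
    if len(allele_cells) > n_allele_columns:
        extra = [c for c in allele_cells[n_allele_columns:] if c != ""]
        if extra:
            raise StructuralError(
                f"row {row_number}: {len(allele_cells)} allele cells, header "
                f"declares {n_allele_columns}"
            )
        allele_cells = allele_cells[:n_allele_columns]
    elif len(allele_cells) < n_allele_columns:
        # spreadsheets drop trailing blanks; treat them as missing calls
        allele_cells += [""] * (n_allele_columns - len(allele_cells))

    calls: dict[str, tuple[Call, ...]] = {}
    for locus in loci:
        first, last = locus.column_span
        slots: list[Call] = []
        for col in range(first, last + 1):
            cell = allele_cells[col - 2]
            if cell in missing_codes:
                slots.append(None)
            elif cell.isascii() and cell.isdigit():
                slots.append(cell)
            else:
                raise ValidationError(
                    f"row {row_number}, column {col} (locus {locus.name!r}): "
                    f"allele label {cell!r} is not numeric and not a missing code"
                )
        calls[locus.name] = tuple(slots)
    return SampleProfile(sample_id=sample_id, calls=calls)


def _detect_delimiter(first_line: str) -> str:
    counts = {d: first_line.count(d) for d in ("\t", ";", ",")}
    best = max(counts, key=counts.__getitem__)
    return best if counts[best] > 0 else ","


def _rows_from_xlsx(path: Path) -> list[list[str]]:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    try:
        sheet = wb.worksheets[0]
        rows: list[list[str]] = []
        for row in sheet.iter_rows(values_only=True):
            cells = []
            for value in row:
                if value is None:
                    cells.append("")
                elif isinstance(value, float) and value.is_integer():
                    cells.append(str(int(value)))
                else:
                    cells.append(str(value))
            rows.append(cells)
        return rows
    finally:
        wb.close()


def read_genotype_table(
    path: Union[str, Path, io.TextIOBase],
    *,
    delimiter: Optional[str] = None,
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
) -> GenotypeTable:
    """Parse a genotype table from delimited text (or ``.xlsx``).

    Parameters
    ----------
    path
        File path or an open text stream.  Paths ending in ``.xlsx`` are
        read through openpyxl; everything else is delimited text.
    delimiter
        Cell delimiter; autodetected among tab / semicolon / comma when None.
    missing_codes
        Cell values normalised to the missing marker (default ``"0"`` and
        the empty cell).

    Returns
    -------
    GenotypeTable
        Validated table preserving file order of loci and samples.
    """
    if isinstance(path, (str, Path)) and str(path).lower().endswith(".xlsx"):
        raw_rows = _rows_from_xlsx(Path(path))
    else:
        if isinstance(path, (str, Path)):
            text = Path(path).read_text(encoding="utf-8")
        else:
            text = path.read()
        # split only on true newlines: str.splitlines would also split on
        # Unicode separators (U+001C..001E, U+0085, ...) inside bad cells
        lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
        if not lines or not lines[0].strip():
            raise StructuralError("input has no header row")
        if delimiter is None:
            delimiter = _detect_delimiter(lines[0])
        raw_rows = list(csv.reader(lines, delimiter=delimiter))

    raw_rows = [row for row in raw_rows if any(c.strip() for c in row)]
    if not raw_rows:
        raise StructuralError("input has no header row")

    loci = _parse_header(raw_rows[0])
    n_allele_columns = sum(locus.ploidy for locus in loci)
    missing = frozenset(missing_codes)

    samples = tuple(
        _parse_row(i, row, loci, n_allele_columns, missing)
        for i, row in enumerate(raw_rows[1:], start=2)
    )
    table = GenotypeTable(loci=loci, samples=samples)
    table.validate()
    return table


# --------------------------------------------------------------------------
# Writing


def table_rows(
    table: GenotypeTable,
    *,
    missing_code: str = DEFAULT_MISSING_OUTPUT,
    id_header: str = "Sample",
) -> list[list[str]]:
    """The table as rows of cells (header first), locus names repeated."""
    header = [id_header]
    for locus in table.loci:
        header.extend([locus.name] * locus.ploidy)
    rows = [header]
    for profile in table.samples:
        row = [profile.sample_id]
        for locus in table.loci:
            row.extend(
                missing_code if call is None else call
                for call in profile.calls[locus.name]
            )
        rows.append(row)
    return rows


def write_genotype_table(
    table: GenotypeTable,
    path: Union[str, Path, io.TextIOBase],
    *,
    delimiter: str = ",",
    missing_code: str = DEFAULT_MISSING_OUTPUT,
) -> None:
    """Write ``table`` as delimited text; reading it back reproduces ``table``."""
    table.validate()
    rows = table_rows(table, missing_code=missing_code)

    def _dump(stream: io.TextIOBase) -> None:
        writer = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
        writer.writerows(rows)

    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _dump(fh)
    else:
        _dump(path)
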