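"""Delimited-table input/output for Darwin Core name and occurrence data.

Tables are tab-separated by default, with a comma fallback selected by the
``.csv`` extension; encoding is strict UTF-8 (undecodable bytes are a hard
error, never silently replaced).  Headers are matched case-insensitively
against the canonical Darwin Core term names; unmapped columns are preserved
in a per-record ``extras`` mapping.  Verbatim field content is kept
byte-for-byte as read — no trimming happens at ingest, normalization is an
explicit downstream operation.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NameRecord",
    "OccurrenceRecord",
    "DwcParseError",
    "NAME_FIELDS",
    "OCCURRENCE_FIELDS",
    "ASSESSMENT_COLUMNS",
    "read_name_table",
    "read_occurrence_table",
    "write_name_table",
    "write_occurrence_table",
    "write_assessment_table",
    "read_assessment_table",
]

#: The six verbatim Darwin Core taxon fields of one name combination.
NAME_FIELDS: tuple[str, ...] = (
    "scientificName",
    "genus",
    "subgenus",
    "specificEpithet",
    "infraspecificEpithet",
    "scientificNameAuthorship",
)

#: Additional fields carried by occurrence records.
OCCURRENCE_FIELDS: tuple[str, ...] = NAME_FIELDS + (
    "basisOfRecord",
    "country",
    "continent",
    "year",
    "class",
    "institutionCode",
)


class DwcParseError(ValueError):
    """Structured parse failure; message always names the offending file."""


@dataclass
class NameRecord:
    """One distinct combination of the six verbatim Darwin Core taxon fields."""

    id: str
    scientificName: str = ""
    genus: str = ""
    subgenus: str = ""
    specificEpithet: str = ""
    infraspecificEpithet: str = ""
    scientificNameAuthorship: str = ""
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class OccurrenceRecord:
    """One occurrence record: the six taxon fields plus modelling covariates."""

    occurrence_id: str
    scientificName: str = ""
    genus: str = ""
    subgenus: str = ""
    specificEpithet: str = ""
    infraspecificEpithet: str = ""
    scientificNameAuthorship: str = ""
    basisOfRecord: str = ""
    country: str = ""
    continent: str = ""
    year: str = ""
    class_: str = ""
    institutionCode: str = ""
    extras: dict[str, str] = field(default_factory=dict)


_ID_ALIASES = {"id", "occurrenceid", "occurrence_id"}
_CLASS_ALIASES = {"class", "class_", "dwc:class"}


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _open_rows(path: Path, delimiter: str) -> list[list[str]]:
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise DwcParseError(f"{path}: cannot read file: {exc}") from exc
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise DwcParseError(f"{path}: not valid UTF-8 at byte {exc.start}") from exc
    return list(csv.reader(io.StringIO(text, newline=""), delimiter=delimiter))


def _map_header(
    header: Sequence[str], known: Sequence[str], path: Path
) -> tuple[dict[int, str], list[int]]:
    """Map column indices to canonical field names, case-insensitively.

    Returns (index -> canonical name, unmapped column indices).  Raises when
    the header contains no recognizable Darwin Core term.
    """
    lower_to_canon = {f.lower(): f for f in known}
    mapping: dict[int, str] = {}
    unmapped: list[int] = []
    for i, col in enumerate(header):
        key = col.strip().lower()
        if key in _ID_ALIASES:
            mapping[i] = "id"
        elif key in _CLASS_ALIASES and "class" in lower_to_canon:
            mapping[i] = "class"
        elif key in lower_to_canon:
            mapping[i] = lower_to_canon[key]
        else:
            unmapped.append(i)
    if not any(v != "id" for v in mapping.values()):
        raise DwcParseError(
            f"{path}: header row contains no recognizable Darwin Core terms: "
            f"{list(header)!r}"
        )
    return mapping, unmapped


def _check_row_width(row: Sequence[str], header: Sequence[str], rownum: int, path: Path) -> None:
    if len(row) != len(header):
        raise DwcParseError(
            f"{path}: row {rownum} has {len(row)} cells, expected {len(header)}"
        )


def _check_unique_ids(ids: list[str], path: Path) -> None:
    seen: set[str] = set()
    dupes: list[str] = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise DwcParseError(f"{path}: duplicate ids: {sorted(set(dupes))}")


def read_name_table(path: str | Path, delimiter: str | None = None) -> list[NameRecord]:
    """Read a table of name combinations; row order is preserved.

    The header is matched case-insensitively against the Darwin Core term
    vocabulary; an ``id`` column is required.  Columns that map to no known
    term are carried through in each record's ``extras``.
    """
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    rows = _open_rows(path, delim)
    if not rows:
        raise DwcParseError(f"{path}: empty file, no header row")
    header = rows[0]
    mapping, unmapped = _map_header(header, NAME_FIELDS, path)
    if "id" not in mapping.values():
        raise DwcParseError(f"{path}: no id column found in header {header!r}")
    records: list[NameRecord] = []
    for rownum, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        _check_row_width(row, header, rownum, path)
        values = {name: row[i] for i, name in mapping.items()}
        extras = {header[i]: row[i] for i in unmapped}
        rec = NameRecord(id=values.pop("id"), extras=extras)
        for name, val in values.items():
            setattr(rec, name, val)
        records.append(rec)
    _check_unique_ids([r.id for r in records], path)
    return records


def read_occurrence_table(
    path: str | Path, delimiter: str | None = None
) -> list[OccurrenceRecord]:
    """Read a table of occurrence records (see :func:`read_name_table`)."""
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    rows = _open_rows(path, delim)
    if not rows:
        raise DwcParseError(f"{path}: empty file, no header row")
    header = rows[0]
    mapping, unmapped = _map_header(header, OCCURRENCE_FIELDS, path)
    if "id" not in mapping.values():
        raise DwcParseError(f"{path}: no id column found in header {header!r}")
    records: list[OccurrenceRecord] = []
    for rownum, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        _check_row_width(row, header, rownum, path)
        values = {name: row[i] for i, name in mapping.items()}
        extras = {header[i]: row[i] for i in unmapped}
        rec = OccurrenceRecord(occurrence_id=values.pop("id"), extras=extras)
        for name, val in values.items():
            setattr(rec, "class_" if name == "class" else name, val)
        records.append(rec)
    _check_unique_ids([r.occurrence_id for r in records], path)
    return records


def _write_rows(path: Path, header: Sequence[str], rows: Iterable[Sequence[str]],
                delimiter: str | None) -> None:
    delim = _delimiter_for(path, delimiter)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_name_table(
    path: str | Path, records: Iterable[NameRecord], delimiter: str | None = None
) -> None:
    """Write name combinations with the canonical header ``id`` + six terms."""
    path = Path(path)
    header = ("id",) + NAME_FIELDS
    rows = [
        [r.id] + [getattr(r, f) for f in NAME_FIELDS] for r in records
    ]
    _write_rows(path, header, rows, delimiter)


def write_occurrence_table(
    path: str | Path, records: Iterable[OccurrenceRecord], delimiter: str | None = None
) -> None:
    """Write occurrence records with the canonical occurrence header."""
    path = Path(path)
    records = list(records)
    extra_cols = sorted({k for r in records for k in r.extras})
    header = ("occurrenceID",) + OCCURRENCE_FIELDS + tuple(extra_cols)
    rows = []
    for r in records:
        row = [r.occurrence_id]
        for f in OCCURRENCE_FIELDS:
            row.append(getattr(r, "class_" if f == "class" else f))
        row.extend(r.extras.get(k, "") for k in extra_cols)
        rows.append(row)
    _write_rows(path, header, rows, delimiter)


# Fixed, documented column order of the assessment output table.  Frozen by a
# golden-file test; do not reorder without a deprecation cycle.
ASSESSMENT_COLUMNS: tuple[str, ...] = (
    "id",
    "constructedscientificname",
    "scientificnameplus",
    "dwcsn-rank",
    "sn-rank",
    "con-rank",
    "hasMisspelling",
    "hasFormatError",
    "hasConceptualError",
    "isSynonym",
    "hasIssue",
    "hasError",
    "con-authcap",
    "con-autherr",
    "sn-inf-missing",
    "con-sgerror",
    "con-rnk",
    "extra-whitespace",
    "epithet-capitalized",
    "genus-uncapitalized",
    "abbreviation-present",
    "qualifier-present",
    "only-infraspecific",
    "validCanonical",
    "validSource",
    "sourceURL",
    "sourceDate",
    "comments",
    "checked",
)


def write_assessment_table(path: str | Path, records, delimiter: str | None = None) -> None:
    """Write assessment records in the documented fixed column order.

    Booleans serialize as ``true``/``false``; the tri-state synonym flag as
    ``yes``/``no``/``indeterminate``.  Re-reading the file with
    :func:`read_assessment_table` yields equal records.
    """
    path = Path(path)
    rows = [rec.to_row() for rec in records]
    _write_rows(path, ASSESSMENT_COLUMNS, rows, delimiter)


def read_assessment_table(path: str | Path, delimiter: str | None = None):
    """Read an assessment table written by :func:`write_assessment_table`."""
    from .issue_detection import AssessmentRecord

    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    rows = _open_rows(path, delim)
    if not rows:
        raise DwcParseError(f"{path}: empty file, no header row")
    header = rows[0]
    if list(header) != list(ASSESSMENT_COLUMNS):
        raise DwcParseError(
            f"{path}: header does not match the assessment column order"
        )
    out = []
    for rownum, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        _check_row_width(row, header, rownum, path)
        out.append(AssessmentRecord.from_row(row))
    return out
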