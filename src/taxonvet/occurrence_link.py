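"""Linking names to occurrence records and standardizing model covariates.

Name combinations and occurrence records are joined on a taxon-name key built
from the concatenation of the six verbatim Darwin Core fields, separated by a
non-printing unit separator so the key is injective on real data.  The join is
an inner join on verbatim bytes — identical field tuples and nothing else.

Occurrence covariates are standardized for the driver models:
``basisOfRecord`` is mapped to the Darwin Core controlled vocabulary and
restricted to FossilSpecimen and PreservedSpecimen; country/continent are
mapped to seven geographic regions (Antarctica excluded); the taxonomic class
is collapsed to five clades, with "Fishes" grouping the fish classes; the
year must parse as a plausible 4-digit collection year.  Records failing any
step are excluded with a machine-readable reason, applied in the documented
order basisOfRecord → region → year → clade.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .dwc_io import NAME_FIELDS, NameRecord, OccurrenceRecord

__all__ = [
    "KEY_SEPARATOR",
    "REGIONS",
    "CLADES",
    "FISH_CLASSES",
    "CovariateVector",
    "Exclusion",
    "LinkResult",
    "make_name_key",
    "link_occurrences",
    "load_region_map",
    "standardize_covariates",
    "standardize_table",
    "compute_institution_counts",
]

#: Non-printing field separator for the taxon-name key (ASCII unit separator).
KEY_SEPARATOR = "\x1f"

REGIONS = (
    "Africa",
    "Asia",
    "Australasia",
    "Europe",
    "North America",
    "Oceania",
    "South America",
)

CLADES = ("Amphibia", "Aves", "Mammalia", "Reptilia", "Fishes")

#: Classes collapsed into the "Fishes" clade.
FISH_CLASSES = frozenset(
    {
        "Actinopterygii",
        "Cephalaspidomorphi",
        "Conodonta",
        "Elasmobranchii",
        "Holocephali",
        "Myxini",
        "Placodermi",
        "Sarcopterygii",
    }
)

# Darwin Core recommended basisOfRecord vocabulary; matching is case- and
# separator-insensitive, unknown values are excluded, never guessed.
_BASIS_VOCABULARY = {
    "preservedspecimen": "PreservedSpecimen",
    "fossilspecimen": "FossilSpecimen",
    "livingspecimen": "LivingSpecimen",
    "humanobservation": "HumanObservation",
    "machineobservation": "MachineObservation",
    "materialsample": "MaterialSample",
    "occurrence": "Occurrence",
}

_RETAINED_BASIS = ("FossilSpecimen", "PreservedSpecimen")


@dataclass(frozen=True)
class CovariateVector:
    """Standardized covariates of one retained occurrence record."""

    basisOfRecord: str
    region: str
    clade: str
    year: int
    institutionRecords: int


@dataclass(frozen=True)
class Exclusion:
    """A record excluded from modelling, with its single primary reason."""

    occurrence_id: str
    reason: str  # basisOfRecord | region | year | clade
    detail: str = ""


def make_name_key(record: Union[NameRecord, OccurrenceRecord]) -> str:
    """Deterministic key from the six verbatim taxon fields.

    Equal field tuples map to equal keys and vice versa.  Raises if a field
    contains the separator (unreachable for real data, which never carries
    the non-printing unit separator).
    """
    values = [getattr(record, f) for f in NAME_FIELDS]
    for v in values:
        if KEY_SEPARATOR in v:
            raise ValueError(
                "field contains the reserved key separator; cannot build key"
            )
    return KEY_SEPARATOR.join(values)


@dataclass
class LinkResult:
    """Outcome of the name/occurrence inner join."""

    #: (name id, occurrence) pairs of the matched set
    matched: list[tuple[str, OccurrenceRecord]]
    #: per-name matching-occurrence count (0 for unmatched names)
    counts: dict[str, int]
    unmatched_name_ids: list[str]
    unmatched_occurrence_ids: list[str]


def link_occurrences(
    names: Sequence[NameRecord],
    occurrences: Sequence[OccurrenceRecord],
) -> LinkResult:
    """Inner join of names and occurrences on the taxon-name key.

    Duplicate identical occurrences are each counted (no deduplication), and
    the sum of per-name counts equals the size of the matched set.
    """
    key_to_ids: dict[str, list[str]] = {}
    for rec in names:
        key_to_ids.setdefault(make_name_key(rec), []).append(rec.id)
    matched: list[tuple[str, OccurrenceRecord]] = []
    counts: dict[str, int] = {rec.id: 0 for rec in names}
    unmatched_occ: list[str] = []
    for occ in occurrences:
        ids = key_to_ids.get(make_name_key(occ))
        if ids is None:
            unmatched_occ.append(occ.occurrence_id)
            continue
        for name_id in ids:
            matched.append((name_id, occ))
            counts[name_id] += 1
    unmatched_names = [i for i, c in counts.items() if c == 0]
    return LinkResult(
        matched=matched,
        counts=counts,
        unmatched_name_ids=unmatched_names,
        unmatched_occurrence_ids=unmatched_occ,
    )


def load_region_map(path: str | Path | None = None) -> dict[str, str]:
    """Country → region mapping, lowercased keys.

    Ships as an editable tab-delimited data file covering common country
    names; continents map directly by name.  Marine localities without a
    country are not covered and fall out as region exclusions.
    """
    if path is None:
        text = (
            resources.files("taxonvet.data")
            .joinpath("country_regions.tsv")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.reader(io.StringIO(text), delimiter="\t"))
    mapping: dict[str, str] = {}
    for row in rows[1:]:
        if len(row) >= 2 and row[0]:
            mapping[row[0].strip().lower()] = row[1].strip()
    return mapping


def _normalize_basis(value: str) -> str | None:
    key = "".join(c for c in value.lower() if c.isalnum())
    return _BASIS_VOCABULARY.get(key)


def _parse_year(value: str, min_year: int = 1700, max_year: int = 2100) -> int | None:
    v = value.strip()
    if len(v) == 4 and v.isdigit():
        y = int(v)
        if min_year <= y <= max_year:
            return y
    return None


def _resolve_region(
    occ: OccurrenceRecord, region_map: Mapping[str, str]
) -> str | None:
    country = occ.country.strip().lower()
    if country in region_map:
        return region_map[country]
    continent = occ.continent.strip()
    if continent in REGIONS:
        return continent
    # Antarctica (and anything unmapped) resolves to no region
    return None


def _resolve_clade(class_name: str) -> str | None:
    c = class_name.strip()
    if c in ("Amphibia", "Aves", "Mammalia", "Reptilia"):
        return c
    if c in FISH_CLASSES:
        return "Fishes"
    return None


def compute_institution_counts(
    occurrences: Iterable[OccurrenceRecord],
) -> dict[str, int]:
    """Digitally accessible record count per institutionCode, computed from
    the supplied table (self-contained default; pass an external mapping to
    :func:`standardize_covariates` for fidelity to a network-wide census)."""
    return dict(Counter(o.institutionCode for o in occurrences))


def standardize_covariates(
    occ: OccurrenceRecord,
    institution_counts: Mapping[str, int],
    region_map: Mapping[str, str] | None = None,
) -> CovariateVector | Exclusion:
    """Standardize one occurrence record or exclude it with a reason.

    Exclusion reasons are applied in the fixed order basisOfRecord → region
    → year → clade so every excluded record has exactly one primary reason.
    """
    if region_map is None:
        region_map = load_region_map()

    basis = _normalize_basis(occ.basisOfRecord)
    if basis not in _RETAINED_BASIS:
        return Exclusion(occ.occurrence_id, "basisOfRecord", occ.basisOfRecord)

    region = _resolve_region(occ, region_map)
    if region is None:
        return Exclusion(
            occ.occurrence_id, "region", f"{occ.country!r}/{occ.continent!r}"
        )

    year = _parse_year(occ.year)
    if year is None:
        return Exclusion(occ.occurrence_id, "year", occ.year)

    clade = _resolve_clade(occ.class_)
    if clade is None:
        return Exclusion(occ.occurrence_id, "clade", occ.class_)

    n_inst = int(institution_counts.get(occ.institutionCode, 0))
    if n_inst <= 0:
        n_inst = 1
    return CovariateVector(
        basisOfRecord=basis,
        region=region,
        clade=clade,
        year=year,
        institutionRecords=n_inst,
    )


def standardize_table(
    occurrences: Sequence[OccurrenceRecord],
    institution_counts: Mapping[str, int] | None = None,
    region_map: Mapping[str, str] | None = None,
) -> tuple[list[tuple[str, CovariateVector]], list[Exclusion]]:
    """Standardize a whole table; returns (kept (occurrence id, vector) pairs,
    exclusions).  Institution counts default to in-table tallies."""
    if institution_counts is None:
        institution_counts = compute_institution_counts(occurrences)
    if region_map is None:
        region_map = load_region_map()
    kept: list[tuple[str, CovariateVector]] = []
    excluded: list[Exclusion] = []
    for occ in occurrences:
        result = standardize_covariates(occ, institution_counts, region_map)
        if isinstance(result, Exclusion):
            excluded.append(result)
        else:
            kept.append((occ.occurrence_id, result))
    return kept, excluded
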