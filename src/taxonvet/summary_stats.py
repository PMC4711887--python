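"""Prevalence summaries, issue-overlap counts, and effort projection.

The summary table mirrors the standard presentation of name-quality results:
for each category (total, valid name found / not found, has error, has issue,
the four issue classes, indeterminate synonymy) it reports the
name-combination count with its percentage of the assessed total, the
matching-occurrence count with its percentage, and the numbers of distinct
institutions and data sets contributing those occurrences.  Percentages are
stored at one decimal with half-up rounding and always recompute exactly from
the paired counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .issue_detection import AssessmentRecord
from .occurrence_link import LinkResult

__all__ = [
    "SummaryRow",
    "SummaryTable",
    "SUMMARY_CATEGORIES",
    "ISSUE_CLASSES",
    "pct",
    "summarize_issues",
    "issue_overlap",
    "project_effort",
]

SUMMARY_CATEGORIES = (
    "Total",
    "Valid name found",
    "Valid name not found",
    "Has error",
    "Has issue",
    "Misspelling",
    "Format error",
    "Conceptual error",
    "Synonym",
    "Indeterminate",
)

ISSUE_CLASSES = ("misspelling", "format", "conceptual", "synonym")

#: Categories reported on the full assessed set even when dual-resolution
#: records are dropped from the issue rows.
_ALWAYS_FULL = ("Total", "Valid name found", "Valid name not found")


def pct(count: int, total: int) -> float:
    """Percentage at one decimal, half-up rounding; 0.0 for an empty total."""
    if total == 0:
        return 0.0
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryRow:
    names: int
    names_pct: float
    occurrences: int
    occurrences_pct: float
    institutions: int
    datasets: int


@dataclass
class SummaryTable:
    rows: dict[str, SummaryRow] = field(default_factory=dict)

    def __getitem__(self, category: str) -> SummaryRow:
        return self.rows[category]

    def validate(self) -> None:
        """Assert the structural invariants of the table."""
        r = self.rows
        assert (
            r["Valid name found"].names + r["Valid name not found"].names
            == r["Total"].names
        ), "valid found + not found must equal total"
        assert r["Has error"].names <= r["Has issue"].names <= r["Total"].names
        for cat in ("Misspelling", "Format error", "Conceptual error", "Synonym"):
            assert r[cat].names <= r["Has issue"].names
        for cat, row in r.items():
            ref_names = r["Total"].names
            ref_occ = r["Total"].occurrences
            assert row.names_pct == pct(row.names, ref_names), cat
            assert row.occurrences_pct == pct(row.occurrences, ref_occ), cat

    @classmethod
    def from_counts(
        cls,
        name_counts: Mapping[str, int],
        occurrence_counts: Mapping[str, int],
        institutions: Mapping[str, int] | None = None,
        datasets: Mapping[str, int] | None = None,
    ) -> "SummaryTable":
        """Build a table from raw paired counts, recomputing all percentages.

        ``name_counts`` and ``occurrence_counts`` map category names to
        counts and must include ``Total``.
        """
        institutions = institutions or {}
        datasets = datasets or {}
        total_names = name_counts["Total"]
        total_occ = occurrence_counts["Total"]
        rows = {}
        for cat in SUMMARY_CATEGORIES:
            if cat not in name_counts:
                continue
            n = name_counts[cat]
            o = occurrence_counts.get(cat, 0)
            rows[cat] = SummaryRow(
                names=n,
                names_pct=pct(n, total_names),
                occurrences=o,
                occurrences_pct=pct(o, total_occ),
                institutions=institutions.get(cat, 0),
                datasets=datasets.get(cat, 0),
            )
        return cls(rows=rows)

    def to_rows(self) -> list[list[str]]:
        out = [["category", "names", "names_pct", "occurrences",
                "occurrences_pct", "institutions", "datasets"]]
        for cat in SUMMARY_CATEGORIES:
            if cat not in self.rows:
                continue
            r = self.rows[cat]
            out.append([cat, str(r.names), f"{r.names_pct:.1f}",
                        str(r.occurrences), f"{r.occurrences_pct:.1f}",
                        str(r.institutions), str(r.datasets)])
        return out


def _issue_set(rec: AssessmentRecord) -> frozenset[str]:
    issues = set()
    if rec.hasMisspelling:
        issues.add("misspelling")
    if rec.hasFormatError:
        issues.add("format")
    if rec.hasConceptualError:
        issues.add("conceptual")
    if rec.isSynonym == "yes":
        issues.add("synonym")
    return frozenset(issues)


def summarize_issues(
    assessments: Sequence[AssessmentRecord],
    matched: LinkResult | None = None,
    exclude_ids: Iterable[str] = (),
) -> SummaryTable:
    """Build the prevalence summary over a set of assessed name combinations.

    ``exclude_ids`` drops name combinations (e.g. dual-resolution records
    that two vetters could not reconcile) from every row except the first
    three, which always describe the full assessed set.  Occurrence,
    institution and data-set counts come from the matched occurrence set when
    one is supplied; the data-set count uses a pass-through ``datasetName``
    extras column when present.
    """
    if not assessments:
        raise ValueError("cannot summarize an empty assessment collection")
    excluded = set(exclude_ids)
    kept = [a for a in assessments if a.id not in excluded]

    def occ_stats(ids: set[str]) -> tuple[int, int, int]:
        if matched is None:
            return 0, 0, 0
        occs = [occ for name_id, occ in matched.matched if name_id in ids]
        n = len(occs)
        inst = len({o.institutionCode for o in occs if o.institutionCode})
        ds = len(
            {o.extras["datasetName"] for o in occs if o.extras.get("datasetName")}
        )
        return n, inst, ds

    categories: dict[str, set[str]] = {
        "Total": {a.id for a in assessments},
        "Valid name found": {a.id for a in assessments if a.validCanonical},
        "Valid name not found": {a.id for a in assessments if not a.validCanonical},
        "Has error": {a.id for a in kept if a.hasError},
        "Has issue": {a.id for a in kept if a.hasIssue},
        "Misspelling": {a.id for a in kept if a.hasMisspelling},
        "Format error": {a.id for a in kept if a.hasFormatError},
        "Conceptual error": {a.id for a in kept if a.hasConceptualError},
        "Synonym": {a.id for a in kept if a.isSynonym == "yes"},
        "Indeterminate": {a.id for a in kept if a.isSynonym == "indeterminate"},
    }

    total_names = len(assessments)
    total_occ, _, _ = occ_stats(categories["Total"])
    rows: dict[str, SummaryRow] = {}
    for cat, ids in categories.items():
        n_occ, n_inst, n_ds = occ_stats(ids)
        rows[cat] = SummaryRow(
            names=len(ids),
            names_pct=pct(len(ids), total_names),
            occurrences=n_occ,
            occurrences_pct=pct(n_occ, total_occ),
            institutions=n_inst,
            datasets=n_ds,
        )
    table = SummaryTable(rows=rows)
    table.validate()
    return table


def issue_overlap(
    assessments: Sequence[AssessmentRecord],
) -> dict[frozenset[str], int]:
    """Partition issue-bearing combinations into the 15 non-empty subsets of
    {misspelling, format, conceptual, synonym}.

    Every subset key is present (zero counts included); the counts sum to the
    number of combinations with at least one issue.
    """
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(ISSUE_CLASSES) + 1):
        for combo in combinations(ISSUE_CLASSES, r):
            counts[frozenset(combo)] = 0
    for rec in assessments:
        issues = _issue_set(rec)
        if issues:
            counts[issues] += 1
    return counts


def project_effort(
    n_names: int, hours_per_batch: float = 4.0, batch_size: int = 100
) -> int:
    """Person-hours to vet ``n_names`` combinations at a given batch rate.

    Manual vetting proceeds at roughly ``hours_per_batch`` hours per
    ``batch_size`` records (about 2 minutes per typical record); the
    projection is a straight proportional scale-up, rounded half-up to whole
    hours.
    """
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    if n_names < 0:
        raise ValueError("n_names must be non-negative")
    hours = Decimal(n_names) * Decimal(str(hours_per_batch)) / Decimal(batch_size)
    return int(hours.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
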