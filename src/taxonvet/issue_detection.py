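"""Detection and classification of taxon-name quality issues.

Four issue classes are assessed per name combination:

misspelling
    character-level corruption (insertions, deletions, substitutions,
    transpositions) of an otherwise correct name; detected by fuzzy matching
    against the authority within a rank-dependent edit-distance radius.
format error
    violations of name-string form that leave the intended name intact:
    extra whitespace, mis-capitalized genus/epithet/authorship, abbreviations.
Darwin Core conceptual error
    misuse of the standard's field semantics: identification qualifiers
    ("sp.", "cf.", "?") inside name fields, authorship placed in an epithet
    field, a bare binomial in ``scientificName`` when an infraspecific
    epithet is also given, or only the infraspecific epithet populated.
synonymy
    the name resolves to a junior synonym in the authority; an issue but not
    an error, and tri-state (yes / no / indeterminate) because a name absent
    from the authority cannot be judged either way.

The rollups obey two invariants: ``hasIssue`` is true iff any of the four
classes is present (synonymy counting only when definitively *yes*), and
``hasError`` covers the three error classes, excluding synonymy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .authority import Authority, canonical_case, damerau_levenshtein
from .dwc_io import NameRecord
from .name_assembly import (
    ConvenienceFields,
    Rank,
    build_convenience,
    infer_rank,
    normalize_whitespace,
    split_authorship,
)

__all__ = [
    "DetectionConfig",
    "AssessmentRecord",
    "Resolution",
    "detect_format_issues",
    "detect_conceptual_issues",
    "resolve_name",
    "assess_record",
    "assess_table",
]

# Default identification-qualifier tokens.  The Darwin Core standard assigns
# these to identificationQualifier; their presence inside a name field is a
# conceptual error.  "sp.", "cf." and "?" are the canonical offenders; the
# rest are conservative extensions, individually removable via config.
DEFAULT_QUALIFIERS: tuple[str, ...] = ("sp.", "spp.", "ssp.", "cf.", "aff.", "nr.", "?")


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds and token lists for issue detection."""

    qualifier_tokens: tuple[str, ...] = DEFAULT_QUALIFIERS
    #: flag a trailing bare "sp" (no period) as a qualifier as well
    qualifier_bare_sp: bool = True
    #: fuzzy radius per token count; None entries fall back to default_max_dist
    max_dist_uninomial: int = 1
    max_dist_binomial: int = 2
    max_dist_trinomial: int = 3

    def max_dist_for(self, name: str) -> int:
        n = len(name.split())
        if n <= 1:
            return self.max_dist_uninomial
        if n == 2:
            return self.max_dist_binomial
        return self.max_dist_trinomial

    @classmethod
    def from_file(cls, path) -> "DetectionConfig":
        """Load thresholds and token lists from a YAML mapping.

        Recognized keys mirror the dataclass fields; unknown keys are an
        error so typos do not silently fall back to defaults.
        """
        import yaml
        from pathlib import Path

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown detection config keys: {sorted(unknown)}")
        if "qualifier_tokens" in data:
            data["qualifier_tokens"] = tuple(data["qualifier_tokens"])
        return cls(**data)


@dataclass
class Resolution:
    """Outcome of resolving one name combination against the authority."""

    valid_canonical: str = ""
    is_synonym: str = "indeterminate"  # yes | no | indeterminate
    has_misspelling: bool = False
    valid_source: str = ""
    source_url: str = ""
    source_date: str = ""
    corrections: int = 0
    comments: list[str] = field(default_factory=list)


@dataclass
class AssessmentRecord:
    """Full per-combination assessment: flags, resolution, provenance."""

    id: str
    convenience: ConvenienceFields
    hasMisspelling: bool = False
    hasFormatError: bool = False
    hasConceptualError: bool = False
    isSynonym: str = "indeterminate"  # yes | no | indeterminate
    hasIssue: bool = False
    hasError: bool = False
    # granular format flags
    con_authcap: bool = False
    extra_whitespace: bool = False
    epithet_capitalized: bool = False
    genus_uncapitalized: bool = False
    abbreviation_present: bool = False
    # granular conceptual flags
    con_autherr: bool = False
    sn_inf_missing: bool = False
    con_sgerror: bool = False
    con_rnk: bool = False
    qualifier_present: bool = False
    only_infraspecific: bool = False
    # resolution output
    validCanonical: str = ""
    validSource: str = ""
    sourceURL: str = ""
    sourceDate: str = ""
    comments: str = ""
    checked: str = "bronze"

    def to_row(self) -> list[str]:
        b = lambda v: "true" if v else "false"
        return [
            self.id,
            self.convenience.constructedscientificname,
            self.convenience.scientificnameplus,
            self.convenience.dwcsn_rank.value,
            self.convenience.sn_rank.value,
            self.convenience.con_rank.value,
            b(self.hasMisspelling),
            b(self.hasFormatError),
            b(self.hasConceptualError),
            self.isSynonym,
            b(self.hasIssue),
            b(self.hasError),
            b(self.con_authcap),
            b(self.con_autherr),
            b(self.sn_inf_missing),
            b(self.con_sgerror),
            b(self.con_rnk),
            b(self.extra_whitespace),
            b(self.epithet_capitalized),
            b(self.genus_uncapitalized),
            b(self.abbreviation_present),
            b(self.qualifier_present),
            b(self.only_infraspecific),
            self.validCanonical,
            self.validSource,
            self.sourceURL,
            self.sourceDate,
            self.comments,
            self.checked,
        ]

    @classmethod
    def from_row(cls, row: Sequence[str]) -> "AssessmentRecord":
        t = lambda v: v == "true"
        conv = ConvenienceFields(
            constructedscientificname=row[1],
            scientificnameplus=row[2],
            dwcsn_rank=Rank(row[3]),
            sn_rank=Rank(row[4]),
            con_rank=Rank(row[5]),
        )
        return cls(
            id=row[0],
            convenience=conv,
            hasMisspelling=t(row[6]),
            hasFormatError=t(row[7]),
            hasConceptualError=t(row[8]),
            isSynonym=row[9],
            hasIssue=t(row[10]),
            hasError=t(row[11]),
            con_authcap=t(row[12]),
            con_autherr=t(row[13]),
            sn_inf_missing=t(row[14]),
            con_sgerror=t(row[15]),
            con_rnk=t(row[16]),
            extra_whitespace=t(row[17]),
            epithet_capitalized=t(row[18]),
            genus_uncapitalized=t(row[19]),
            abbreviation_present=t(row[20]),
            qualifier_present=t(row[21]),
            only_infraspecific=t(row[22]),
            validCanonical=row[23],
            validSource=row[24],
            sourceURL=row[25],
            sourceDate=row[26],
            comments=row[27],
            checked=row[28],
        )


_ABBREV_RE = re.compile(r"(?:^|\s)[A-Za-z]\.(?:\s|$)")
_WS_PROBLEM_RE = re.compile(r"^\s|\s$|\s\s|[\t\n\r]")


def _has_ws_problem(text: str) -> bool:
    return bool(text) and bool(_WS_PROBLEM_RE.search(text))


def _authorship_miscapitalized(authorship: str) -> bool:
    """Authorship surnames must start uppercase (ICZN usage)."""
    for tok in authorship.replace("(", " ").replace(")", " ").split():
        bare = tok.strip(",.&")
        if not bare or bare.isdigit():
            continue
        if bare.lower() in ("and", "et", "ex", "in", "von", "van", "de", "del", "la"):
            continue
        if bare[:1].isalpha() and bare[:1].islower():
            return True
    return False


def detect_format_issues(
    record: NameRecord, convenience: ConvenienceFields | None = None
) -> tuple[dict[str, bool], dict[str, str]]:
    """Detect format problems; return (flags, normalized name strings).

    The verbatim record is never mutated: the second element of the return
    value carries whitespace- and case-normalized copies of the name strings
    for downstream matching.
    """
    conv = convenience or build_convenience(record)
    flags = {
        "extra_whitespace": False,
        "genus_uncapitalized": False,
        "epithet_capitalized": False,
        "con_authcap": False,
        "abbreviation_present": False,
    }

    name_fields = (
        record.scientificName,
        record.genus,
        record.subgenus,
        record.specificEpithet,
        record.infraspecificEpithet,
        record.scientificNameAuthorship,
    )
    if any(_has_ws_problem(f) for f in name_fields):
        flags["extra_whitespace"] = True

    genus = record.genus.strip()
    if genus and genus[:1].islower():
        flags["genus_uncapitalized"] = True
    for ep in (record.specificEpithet, record.infraspecificEpithet):
        ep = ep.strip()
        if ep and ep[:1].isupper():
            flags["epithet_capitalized"] = True

    # scientificName-side checks: first token is the genus, tokens in epithet
    # position must be lowercase.  Authorship tokens are stripped first.
    sn_tokens, sn_auth = split_authorship(record.scientificName)
    if sn_tokens and sn_tokens[0][:1].islower():
        flags["genus_uncapitalized"] = True
    for tok in sn_tokens[1:]:
        if tok.startswith("("):
            continue  # parenthesized subgenus
        # in scientificName the subgenus convention is parenthesized, so any
        # bare capitalized token in epithet position is a capitalization error
        if tok[:1].isupper():
            flags["epithet_capitalized"] = True

    authorship_texts = [record.scientificNameAuthorship]
    if sn_auth:
        authorship_texts.append(" ".join(sn_auth))
    if any(_authorship_miscapitalized(t) for t in authorship_texts if t.strip()):
        flags["con_authcap"] = True

    for text in (record.scientificName, record.genus, conv.constructedscientificname):
        if _ABBREV_RE.search(text):
            flags["abbreviation_present"] = True

    normalized = {
        "scientificName": canonical_case(normalize_whitespace(record.scientificName)),
        "constructedscientificname": canonical_case(
            normalize_whitespace(conv.constructedscientificname)
        ),
        "scientificnameplus": canonical_case(
            normalize_whitespace(conv.scientificnameplus)
        ),
    }
    return flags, normalized


_AUTHORLIKE_IN_EPITHET_RE = re.compile(r"[A-Z(),]|\d")


def detect_conceptual_issues(
    record: NameRecord,
    convenience: ConvenienceFields | None = None,
    config: DetectionConfig = DetectionConfig(),
) -> dict[str, bool]:
    """Detect Darwin Core conceptual errors (field-semantics misuse)."""
    conv = convenience or build_convenience(record)
    flags = {
        "qualifier_present": False,
        "con_autherr": False,
        "sn_inf_missing": False,
        "only_infraspecific": False,
        "con_sgerror": False,
        "con_rnk": False,
    }

    qualifier_set = {q.lower() for q in config.qualifier_tokens}
    taxon_fields = (
        record.scientificName,
        record.genus,
        record.subgenus,
        record.specificEpithet,
        record.infraspecificEpithet,
    )
    for text in taxon_fields:
        toks = [t.lower() for t in text.split()]
        if any(t in qualifier_set or "?" in t for t in toks):
            flags["qualifier_present"] = True
        if config.qualifier_bare_sp and toks and toks[-1] == "sp":
            flags["qualifier_present"] = True

    # authorship content inside an epithet field
    for ep in (record.specificEpithet, record.infraspecificEpithet):
        toks = ep.split()
        if len(toks) > 1 and any(_AUTHORLIKE_IN_EPITHET_RE.search(t) for t in toks[1:]):
            flags["con_autherr"] = True
        if toks and _AUTHORLIKE_IN_EPITHET_RE.search(toks[0][1:]):
            flags["con_autherr"] = True

    # binomial-only scientificName while an infraspecific epithet is given
    infra = record.infraspecificEpithet.strip()
    if record.scientificName.strip() and infra:
        if infra not in record.scientificName.split():
            flags["sn_inf_missing"] = True

    # only the infraspecific epithet populated among the atomic fields
    if infra and not any(
        f.strip()
        for f in (
            record.genus,
            record.subgenus,
            record.specificEpithet,
            record.scientificNameAuthorship,
        )
    ):
        flags["only_infraspecific"] = True

    # malformed subgenus: anything but a single (optionally parenthesized)
    # capitalized latin word
    sg = record.subgenus.strip()
    if sg:
        bare = sg[1:-1] if (sg.startswith("(") and sg.endswith(")")) else sg
        if not re.fullmatch(r"[A-Z][a-z-]+", bare):
            flags["con_sgerror"] = True

    # rank inconsistency of the constructed name, judged on a normalized copy
    # so pure capitalization/whitespace problems stay with the format class
    con_norm = canonical_case(
        normalize_whitespace(conv.constructedscientificname)
    )
    if con_norm and infer_rank(con_norm) is Rank.INDETERMINATE:
        flags["con_rnk"] = True

    return flags


def _strip_to_canonical(
    name: str, config: DetectionConfig = DetectionConfig()
) -> str:
    """Reduce a name string to its canonical core for authority matching.

    Drops authorship tokens and identification-qualifier tokens (those are
    charged to their own detectors, and a qualifier must not block the
    resolution of the underlying name), then normalizes case and whitespace.
    """
    name_tokens, _ = split_authorship(normalize_whitespace(name))
    qualifiers = {q.lower() for q in config.qualifier_tokens}
    kept = [
        t
        for t in name_tokens
        if t.lower() not in qualifiers
        and "?" not in t
        and not (config.qualifier_bare_sp and t.lower() in ("sp", "spp"))
    ]
    return canonical_case(" ".join(kept))


_ABBREV_GENUS_RE = re.compile(r"^[A-Za-z]\.$")


def _expand_abbreviated_genus(
    cand: str, authority: Authority, config: DetectionConfig
) -> tuple:
    """Match a name with an abbreviated genus ("P. major") to the authority.

    Candidates share the genus initial and match the remaining tokens either
    exactly or within the fuzzy radius (the latter charges misspelling).
    Ties break deterministically: smaller distance, accepted before synonym,
    lexicographic.  Returns (entry, tail_distance) or (None, 0).
    """
    tokens = cand.split()
    if not tokens or not _ABBREV_GENUS_RE.match(tokens[0]) or len(tokens) < 2:
        return None, 0
    initial = tokens[0][0].upper()
    tail = " ".join(tokens[1:])
    max_dist = config.max_dist_for(cand)
    hits = []
    for entry in authority:
        etoks = entry.canonical.split()
        if len(etoks) != len(tokens) or not etoks[0].startswith(initial):
            continue
        etail = " ".join(etoks[1:])
        dist = 0 if etail == tail else damerau_levenshtein(etail, tail)
        if dist <= max_dist:
            hits.append((dist, entry.status != "accepted", entry.canonical, entry))
    if not hits:
        return None, 0
    hits.sort(key=lambda h: h[:3])
    return hits[0][3], hits[0][0]


@dataclass
class _CandidateHit:
    canonical: str
    accepted: str
    is_synonym: bool
    corrections: int
    source: str
    source_url: str
    source_date: str
    from_constructed: bool


def resolve_name(
    constructed: str,
    scientificname_plus: str,
    authority: Authority,
    config: DetectionConfig = DetectionConfig(),
) -> Resolution:
    """Resolve the two convenience strings to a valid canonical name.

    Each candidate is canonical-normalized (authorship stripped, case and
    whitespace fixed) and tried against the authority: exact accepted hit,
    exact synonym hit (one-hop resolution), then fuzzy lookup within the
    rank-dependent radius — a fuzzy hit charges ``hasMisspelling`` and a
    fuzzy hit on a synonym entry charges both misspelling and synonymy.
    When the two candidates disagree, the one reaching an accepted name with
    fewer corrections wins, with atomic fields (the constructed name)
    preferred on ties; the disagreement is logged in comments.  If neither
    candidate reaches the authority the synonym status is indeterminate and
    no valid canonical is reported.
    """
    hits: list[_CandidateHit] = []
    comments: list[str] = []
    for raw, from_con in ((constructed, True), (scientificname_plus, False)):
        cand = _strip_to_canonical(raw, config)
        if not cand:
            continue
        entry = authority.lookup_exact(cand)
        dist = 0
        if entry is None:
            entry, dist = _expand_abbreviated_genus(cand, authority, config)
            if entry is not None:
                comments.append(
                    f"abbreviated genus in {cand!r} expanded to {entry.canonical!r}"
                )
        if entry is None:
            fuzzy = authority.lookup_fuzzy(cand, config.max_dist_for(cand))
            if not fuzzy:
                continue
            entry, dist = fuzzy[0]
            if len(fuzzy) > 1 and fuzzy[1][1] == dist:
                comments.append(
                    f"ambiguous fuzzy match for {cand!r}: kept {entry.canonical!r}"
                )
        accepted = authority.resolve(entry)
        hits.append(
            _CandidateHit(
                canonical=entry.canonical,
                accepted=accepted.canonical,
                is_synonym=entry.status == "synonym",
                corrections=dist,
                source=accepted.source,
                source_url=accepted.source_url,
                source_date=accepted.source_date,
                from_constructed=from_con,
            )
        )

    if not hits:
        return Resolution(comments=comments)

    # fewer corrections first; atomic-field candidate wins ties
    hits.sort(key=lambda h: (h.corrections, not h.from_constructed))
    best = hits[0]
    if len(hits) == 2 and hits[0].accepted != hits[1].accepted:
        comments.append(
            "candidates disagree: constructed and scientificnameplus resolve to "
            f"{hits[0].accepted!r} vs {hits[1].accepted!r}; kept {best.accepted!r}"
        )
    if best.is_synonym and best.corrections > 0:
        comments.append("misspelled junior synonym: corrected then resolved")

    return Resolution(
        valid_canonical=best.accepted,
        is_synonym="yes" if best.is_synonym else "no",
        has_misspelling=best.corrections > 0,
        valid_source=best.source,
        source_url=best.source_url,
        source_date=best.source_date,
        corrections=best.corrections,
        comments=comments,
    )


def assess_record(
    record: NameRecord,
    authority: Authority,
    config: DetectionConfig = DetectionConfig(),
) -> AssessmentRecord:
    """Run the full assessment of one name combination.

    Composes name assembly, the format and conceptual detectors, and name
    resolution, then sets the ``hasIssue``/``hasError`` rollups.  A
    constructed name containing only authorship is not itself invalid unless
    the authorship is malformed; resolution then relies on the
    ``scientificnameplus`` candidate alone.
    """
    conv = build_convenience(record)
    fmt_flags, normalized = detect_format_issues(record, conv)
    con_flags = detect_conceptual_issues(record, conv, config)

    del normalized  # resolution strips authorship before case-normalizing
    constructed_candidate = conv.constructedscientificname
    # authorship-only constructed name: nothing to resolve on that side
    atomic_names = (record.genus, record.subgenus, record.specificEpithet,
                    record.infraspecificEpithet)
    if not any(f.strip() for f in atomic_names):
        constructed_candidate = ""

    resolution = resolve_name(
        constructed_candidate, conv.scientificnameplus, authority, config
    )

    rec = AssessmentRecord(
        id=record.id,
        convenience=conv,
        hasMisspelling=resolution.has_misspelling,
        isSynonym=resolution.is_synonym,
        validCanonical=resolution.valid_canonical,
        validSource=resolution.valid_source,
        sourceURL=resolution.source_url,
        sourceDate=resolution.source_date,
        comments="; ".join(resolution.comments),
        **fmt_flags,
        **con_flags,
    )
    rec.hasFormatError = any(fmt_flags.values())
    rec.hasConceptualError = any(con_flags.values())
    rec.hasError = rec.hasMisspelling or rec.hasFormatError or rec.hasConceptualError
    rec.hasIssue = rec.hasError or rec.isSynonym == "yes"
    return rec


def assess_table(
    records: Iterable[NameRecord],
    authority: Authority,
    config: DetectionConfig = DetectionConfig(),
) -> list[AssessmentRecord]:
    """Assess every record in a table, preserving order."""
    return [assess_record(r, authority, config) for r in records]
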