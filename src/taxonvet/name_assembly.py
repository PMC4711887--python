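"""Construction of convenience name strings and taxon-rank inference.

Aggregated occurrence data carry a scientific name twice: once as the free-text
``scientificName`` field and once atomized into ``genus``, ``subgenus``,
``specificEpithet``, ``infraspecificEpithet`` and ``scientificNameAuthorship``.
Neither representation is reliable on its own, so two derived strings are built
for every name combination:

``constructedscientificname``
    the space-separated concatenation of the five atomic fields, skipping empty
    ones.  When *only* the infraspecific epithet is populated the constructed
    name is left blank — that field pattern signals a provider convention in
    which the full name lives in ``scientificName`` and only the terminal
    epithet is atomized, and gluing the bare epithet to nothing would produce a
    meaningless string.

``scientificnameplus``
    ``scientificName`` extended with the infraspecific epithet when both are
    populated and the epithet is not already a whole token of the name; some
    providers populate ``scientificName`` with nothing more than a binomial
    even when an infraspecific epithet is given.

Both strings, and the verbatim ``scientificName``, are assigned a terminal
taxon rank by counting name tokens after authorship-like tokens are stripped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .dwc_io import NameRecord

__all__ = [
    "Rank",
    "ConvenienceFields",
    "build_constructed_name",
    "build_scientificname_plus",
    "build_convenience",
    "infer_rank",
    "split_authorship",
    "normalize_whitespace",
]


class Rank(str, Enum):
    """Terminal taxon rank of a name string."""

    NONE = "none"
    HIGHER = "higher"
    GENUS = "genus"
    SUBGENUS = "subgenus"
    SPECIES = "species"
    INFRASPECIFIC = "infraspecific"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ConvenienceFields:
    """The two constructed name strings plus their rank determinations."""

    constructedscientificname: str
    scientificnameplus: str
    dwcsn_rank: Rank
    sn_rank: Rank
    con_rank: Rank


_YEAR_RE = re.compile(r"^\(?\d{4}[a-z]?\)?[,.]?$")


def normalize_whitespace(text: str) -> str:
    """Collapse runs of whitespace to single spaces and strip the ends."""
    return " ".join(text.split())


def build_constructed_name(record: "NameRecord") -> str:
    """Space-separated concatenation of the five atomic name fields.

    Empty fields are skipped so the result carries no doubled or dangling
    spaces.  If the infraspecific epithet is the only populated field the
    result is the empty string (see module docstring).
    """
    parts = [
        record.genus,
        record.subgenus,
        record.specificEpithet,
        record.infraspecificEpithet,
        record.scientificNameAuthorship,
    ]
    populated = [normalize_whitespace(p) for p in parts if p.strip()]
    only_infra = (
        bool(record.infraspecificEpithet.strip())
        and not record.genus.strip()
        and not record.subgenus.strip()
        and not record.specificEpithet.strip()
        and not record.scientificNameAuthorship.strip()
    )
    if only_infra:
        return ""
    return " ".join(populated)


def build_scientificname_plus(record: "NameRecord") -> str:
    """``scientificName`` extended with a missing infraspecific epithet.

    The epithet is appended only when both fields are populated and the
    epithet does not already appear as a whole (case-sensitive) token of
    ``scientificName``; otherwise the verbatim ``scientificName`` is returned
    unchanged.  The result is never shorter than ``scientificName``.
    """
    sn = record.scientificName
    infra = record.infraspecificEpithet.strip()
    if not sn.strip() or not infra:
        return sn
    if infra in sn.split():
        return sn
    return normalize_whitespace(sn) + " " + infra


def _is_authorship_token(token: str, n_lower_before: int) -> bool:
    # Conservative, auditable heuristic: a token is authorship-like if it is
    # a 4-digit year, starts with "(", contains ",", or is a capitalized
    # token appearing after at least two lowercase epithet tokens.
    if _YEAR_RE.match(token):
        return True
    if token.startswith("("):
        return True
    if "," in token:
        return True
    if token[:1].isupper() and n_lower_before >= 2:
        return True
    return False


def split_authorship(name: str) -> tuple[list[str], list[str]]:
    """Split a name string into (name tokens, authorship tokens).

    Scans left to right; the first authorship-like token and everything after
    it belong to the authorship.  Subgenus parentheses are not treated as
    authorship: a parenthesized token in second position directly after the
    genus is kept with the name.
    """
    tokens = normalize_whitespace(name).split()
    name_tokens: list[str] = []
    n_lower = 0
    for i, tok in enumerate(tokens):
        is_subgenus_slot = (
            i == 1
            and tok.startswith("(")
            and tok.endswith(")")
            and tok[1:-1][:1].isupper()
        )
        if not is_subgenus_slot and _is_authorship_token(tok, n_lower):
            return name_tokens, tokens[i:]
        name_tokens.append(tok)
        if tok[:1].islower():
            n_lower += 1
    return name_tokens, []


_WORD_RE = re.compile(r"^[A-Za-z][a-z'à-ÿ-]*\.?$")


def infer_rank(name: str) -> Rank:
    """Classify the terminal rank of a name string from its token shape.

    Authorship tokens are stripped first; the remaining tokens are counted:
    a single capitalized token is a genus, two tokens a species, three or
    more an infraspecific name.  A parenthesized or bare capitalized token in
    second position followed by further epithets counts as a subgenus, not an
    epithet.  Token mixtures that fit none of these shapes (digits inside
    words, capitalized tokens in epithet position) are ``indeterminate``.
    """
    name_tokens, _ = split_authorship(name)
    if not name_tokens:
        return Rank.NONE
    for tok in name_tokens:
        bare = tok[1:-1] if (tok.startswith("(") and tok.endswith(")")) else tok
        if not bare or not _WORD_RE.match(bare):
            return Rank.INDETERMINATE

    # Identify a subgenus in second position: parenthesized, or capitalized
    # and followed by at least one lowercase epithet.
    toks = list(name_tokens)
    has_subgenus = False
    if len(toks) >= 2:
        second = toks[1]
        if second.startswith("(") and second.endswith(")"):
            has_subgenus = True
        elif second[:1].isupper() and len(toks) >= 3 and toks[2][:1].islower():
            has_subgenus = True
    epithets = toks[2:] if has_subgenus else toks[1:]
    # Capitalized tokens in epithet position do not fit any rank shape.
    if any(t[:1].isupper() for t in epithets):
        return Rank.INDETERMINATE
    n_epithets = len(epithets)
    if n_epithets == 0:
        return Rank.SUBGENUS if has_subgenus else Rank.GENUS
    if n_epithets == 1:
        return Rank.SPECIES
    return Rank.INFRASPECIFIC


def build_convenience(record: "NameRecord") -> ConvenienceFields:
    """Construct both convenience strings and all three rank determinations."""
    constructed = build_constructed_name(record)
    sn_plus = build_scientificname_plus(record)
    return ConvenienceFields(
        constructedscientificname=constructed,
        scientificnameplus=sn_plus,
        dwcsn_rank=infer_rank(record.scientificName),
        sn_rank=infer_rank(sn_plus),
        con_rank=infer_rank(constructed),
    )
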