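"""Local, pluggable taxonomic authority.

The authority is a curated table of canonical names (genus, optional subgenus,
epithets — no authorship) with a status of ``accepted`` or ``synonym`` and, for
synonyms, a pointer to the terminal accepted name.  It is the programmatic
stand-in for consulting online checklists (ITIS, Catalogue of Life, group
specific databases) during manual vetting, and supports three lookups: exact,
fuzzy by Damerau–Levenshtein edit distance, and synonym resolution.

The table must be closed under resolution: every ``acceptedCanonical`` value
appears in the table as an accepted entry, and synonym chains resolve in one
hop (the table stores the terminal accepted name, not intermediate links).
This is verified at load time.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .name_assembly import Rank

try:  # optional accelerator: SIMD Levenshtein used only as a search prefilter
    import edlib as _edlib
except ImportError:  # pragma: no cover
    _edlib = None

__all__ = [
    "AuthorityEntry",
    "Authority",
    "AuthorityError",
    "damerau_levenshtein",
    "edit_distance",
    "canonical_case",
    "default_max_dist",
    "load_authority",
]

AUTHORITY_COLUMNS = (
    "canonical",
    "rank",
    "status",
    "acceptedCanonical",
    "source",
    "sourceURL",
    "sourceDate",
)


class AuthorityError(ValueError):
    """Authority table violates a structural invariant."""


@dataclass(frozen=True)
class AuthorityEntry:
    canonical: str
    rank: Rank
    status: str  # "accepted" | "synonym"
    accepted_canonical: str
    source: str = ""
    source_url: str = ""
    source_date: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("accepted", "synonym"):
            raise AuthorityError(
                f"{self.canonical}: status must be accepted or synonym, "
                f"got {self.status!r}"
            )
        if self.status == "accepted" and self.accepted_canonical != self.canonical:
            raise AuthorityError(
                f"{self.canonical}: accepted entry must point to itself"
            )


def damerau_levenshtein(a: str, b: str) -> int:
    """Unrestricted Damerau–Levenshtein distance between two strings.

    Unit-cost character insertions, deletions, substitutions and
    transpositions (Lowrance–Wagner algorithm).  Unlike the restricted
    "optimal string alignment" variant, this distance is a true metric:
    it is symmetric, zero only for equal strings, and satisfies the
    triangle inequality.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    maxdist = la + lb
    da: dict[str, int] = {}
    # d has two extra border rows/cols for the transposition lookback.
    d = [[0] * (lb + 2) for _ in range(la + 2)]
    d[0][0] = maxdist
    for i in range(la + 1):
        d[i + 1][0] = maxdist
        d[i + 1][1] = i
    for j in range(lb + 1):
        d[0][j + 1] = maxdist
        d[1][j + 1] = j
    for i in range(1, la + 1):
        db = 0
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cb = b[j - 1]
            k = da.get(cb, 0)
            m = db
            if ca == cb:
                cost = 0
                db = j
            else:
                cost = 1
            d[i + 1][j + 1] = min(
                d[i][j] + cost,  # substitution / match
                d[i + 1][j] + 1,  # insertion
                d[i][j + 1] + 1,  # deletion
                d[k][m] + (i - k - 1) + 1 + (j - m - 1),  # transposition
            )
        da[ca] = i
    return d[la + 1][lb + 1]


#: Alias used throughout the package.
edit_distance = damerau_levenshtein


def canonical_case(name: str) -> str:
    """Normalize a name to canonical capitalization for distance comparison.

    First token capitalized (genus), parenthesized second token capitalized
    (subgenus), remaining tokens lowercased (epithets).  Capitalization
    problems are charged to the format detector, never to the edit distance.
    """
    tokens = " ".join(name.split()).split()
    out: list[str] = []
    for i, tok in enumerate(tokens):
        if i == 0:
            out.append(tok[:1].upper() + tok[1:].lower())
        elif tok.startswith("(") and tok.endswith(")") and len(tok) > 2:
            inner = tok[1:-1]
            out.append("(" + inner[:1].upper() + inner[1:].lower() + ")")
        else:
            out.append(tok.lower())
    return " ".join(out)


def default_max_dist(name: str) -> int:
    """Default fuzzy-match radius by name length: 1 for uninomials, 2 for
    binomials, 3 for trinomials and longer."""
    n = len(name.split())
    if n <= 1:
        return 1
    if n == 2:
        return 2
    return 3


class Authority:
    """Indexed collection of :class:`AuthorityEntry`, closed under resolution."""

    def __init__(self, entries: Iterable[AuthorityEntry]):
        self._by_canonical: dict[str, AuthorityEntry] = {}
        for e in entries:
            prev = self._by_canonical.get(e.canonical)
            if prev is not None and prev != e:
                raise AuthorityError(
                    f"duplicate canonical with conflicting content: {e.canonical!r}"
                )
            self._by_canonical[e.canonical] = e
        self._check_closure()

    def _check_closure(self) -> None:
        offenders = []
        for e in self._by_canonical.values():
            target = self._by_canonical.get(e.accepted_canonical)
            if target is None or target.status != "accepted":
                offenders.append(e.canonical)
        if offenders:
            raise AuthorityError(
                "synonyms point to absent or non-accepted names: "
                f"{sorted(offenders)}"
            )

    def __len__(self) -> int:
        return len(self._by_canonical)

    def __iter__(self):
        return iter(self._by_canonical.values())

    @property
    def entries(self) -> list[AuthorityEntry]:
        return list(self._by_canonical.values())

    def lookup_exact(self, name: str) -> AuthorityEntry | None:
        """Case-sensitive exact lookup of a canonical name."""
        return self._by_canonical.get(name)

    def lookup_fuzzy(
        self, name: str, max_dist: int
    ) -> list[tuple[AuthorityEntry, int]]:
        """All entries within ``max_dist`` edits of ``name``.

        Distance is computed on case-normalized copies (see
        :func:`canonical_case`).  Candidates are ordered by distance, then
        accepted before synonym, then lexicographically by canonical name —
        a deterministic tie-break rather than an ambiguity failure; callers
        that care about ties can inspect the full ranked list.
        """
        query = canonical_case(name)
        hits: list[tuple[AuthorityEntry, int]] = []
        for entry in self._by_canonical.values():
            if abs(len(entry.canonical) - len(query)) > max_dist:
                continue
            # plain Levenshtein is at most twice the transposition-aware
            # distance, so a k-limited Levenshtein check culls non-candidates
            # cheaply before the exact computation
            if _edlib is not None:
                lev = _edlib.align(
                    query, entry.canonical, task="distance", k=2 * max_dist
                )["editDistance"]
                if lev == -1:
                    continue
            dist = damerau_levenshtein(query, entry.canonical)
            if dist <= max_dist:
                hits.append((entry, dist))
        hits.sort(key=lambda h: (h[1], h[0].status != "accepted", h[0].canonical))
        return hits

    def resolve(self, entry: AuthorityEntry) -> AuthorityEntry:
        """Follow the accepted-name pointer; idempotent by closure."""
        return self._by_canonical[entry.accepted_canonical]

    @classmethod
    def from_file(cls, path: str | Path, delimiter: str | None = None) -> "Authority":
        path = Path(path)
        delim = delimiter or ("," if path.suffix.lower() == ".csv" else "\t")
        try:
            text = path.read_bytes().decode("utf-8")
        except OSError as exc:
            raise AuthorityError(f"{path}: cannot read: {exc}") from exc
        except UnicodeDecodeError as exc:
            raise AuthorityError(f"{path}: not valid UTF-8") from exc
        rows = list(csv.reader(io.StringIO(text, newline=""), delimiter=delim))
        if not rows:
            raise AuthorityError(f"{path}: empty authority file")
        header = [h.strip() for h in rows[0]]
        idx = {name: header.index(name) for name in AUTHORITY_COLUMNS if name in header}
        if "canonical" not in idx or "status" not in idx:
            raise AuthorityError(
                f"{path}: header must contain at least canonical and status, "
                f"got {header!r}"
            )
        entries = []
        for row in rows[1:]:
            if not row:
                continue

            def get(col: str, default: str = "") -> str:
                i = idx.get(col)
                return row[i] if i is not None and i < len(row) else default

            canonical = get("canonical")
            entries.append(
                AuthorityEntry(
                    canonical=canonical,
                    rank=Rank(get("rank", "species") or "species"),
                    status=get("status"),
                    accepted_canonical=get("acceptedCanonical") or canonical,
                    source=get("source"),
                    source_url=get("sourceURL"),
                    source_date=get("sourceDate"),
                )
            )
        return cls(entries)

    def to_file(self, path: str | Path, delimiter: str | None = None) -> None:
        path = Path(path)
        delim = delimiter or ("," if path.suffix.lower() == ".csv" else "\t")
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
            writer.writerow(AUTHORITY_COLUMNS)
            for e in sorted(self._by_canonical.values(), key=lambda e: e.canonical):
                writer.writerow(
                    [
                        e.canonical,
                        e.rank.value,
                        e.status,
                        e.accepted_canonical,
                        e.source,
                        e.source_url,
                        e.source_date,
                    ]
                )


def load_authority(path: str | Path, delimiter: str | None = None) -> Authority:
    """Load an authority table from a delimited file (see :class:`Authority`)."""
    return Authority.from_file(path, delimiter)
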