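"""Synthetic data with known truth for exercising the assessment pipeline.

Three generators, all fully determined by a seed:

* an authority bank of pronounceable latinized binomials/trinomials, with a
  configurable fraction of junior synonyms created by genus transfer or
  epithet gender swap, always pointing at an accepted name (closed under
  resolution by construction);
* name combinations corrupted by the four issue classes at configured rates —
  the defaults are the prevalences observed in vetted aggregator data
  (misspelling 12.9%, format 8.9%, conceptual 13.7%, synonymy 27%) — with a
  truth label recording exactly what was injected;
* occurrence tables whose covariates (record type, region, clade, year,
  institutional record volume) follow realistic marginal distributions and
  whose binary issue outcomes can be drawn from a known logit model, so
  coefficient recovery can be tested against the truth.

Issue classes combine independently per name, which exercises all fifteen
overlap cells of the four-class Venn partition.  Names are built from
syllable templates over a latinate alphabet; no real taxon names are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .authority import Authority, AuthorityEntry, damerau_levenshtein
from .dwc_io import NameRecord, OccurrenceRecord
from .name_assembly import Rank

__all__ = [
    "GeneratorConfig",
    "TruthLabel",
    "Bundle",
    "generate_authority",
    "corrupt_name",
    "simulate_covariates",
    "simulate_issue_outcomes",
    "generate_dataset",
]

_CONSONANTS = list("bcdfglmnprstvz")
_VOWELS = list("aeiou")

# epithet gender-ending swaps used to mint plausible junior synonyms
_GENDER_SWAPS = (("us", "a"), ("er", "ra"), ("is", "e"), ("or", "rix"))

_SURNAMES = (
    "Linden", "Moravec", "Castello", "Brandt", "Sowerby", "Delacour",
    "Ferreira", "Okada", "Navarro", "Whitfield", "Santos", "Keulen",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and rates of the synthetic bundle; the seed fixes everything."""

    seed: int = 0
    # authority shape; the default bank is large enough that each generated
    # name combination can reference a distinct species
    n_genera: int = 150
    species_per_genus: int = 6
    subspecies_rate: float = 0.15
    synonym_rate: float = 0.3
    # issue rates per class (name-combination prevalences in vetted data)
    rate_misspelling: float = 0.129
    rate_format: float = 0.089
    rate_conceptual: float = 0.137
    rate_synonym: float = 0.27
    #: probability that a misspelling applies 2 edits rather than 1
    second_edit_rate: float = 0.3
    # occurrence shape
    n_names: int = 1000
    mean_occurrences_per_name: float = 27.0
    n_institutions: int = 40
    year_range: tuple[int, int] = (1900, 2015)
    #: true logit coefficients used when issue outcomes are simulated from
    #: covariates (keys must match design-matrix columns)
    true_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in (
            self.rate_misspelling,
            self.rate_format,
            self.rate_conceptual,
            self.rate_synonym,
            self.subspecies_rate,
            self.synonym_rate,
            self.second_edit_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {r}")


@dataclass
class TruthLabel:
    """What was injected into one generated name combination."""

    id: str
    clean_canonical: str
    issues: frozenset[str]  # subset of {misspelling, format, conceptual, synonym}
    synonym_used: str = ""
    n_edits: int = 0
    format_kind: str = ""
    conceptual_kind: str = ""
    provider_style: str = ""  # atomic | scientificName | both


@dataclass
class Bundle:
    """End-to-end synthetic data set with ground truth."""

    names: list[NameRecord]
    occurrences: list[OccurrenceRecord]
    authority: Authority
    truth: dict[str, TruthLabel]
    config: GeneratorConfig


def _syllable(rng: np.random.Generator) -> str:
    return rng.choice(_CONSONANTS) + rng.choice(_VOWELS)


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


def _genus_name(rng: np.random.Generator) -> str:
    w = _word(rng, int(rng.integers(2, 4)))
    return w.capitalize()


def _epithet(rng: np.random.Generator) -> str:
    base = _word(rng, int(rng.integers(2, 4)))
    # bias towards swappable endings so gender-swap synonyms are available
    if rng.random() < 0.5:
        base = base + rng.choice(["us", "er", "is", "or"])
    return base


def _authorship(rng: np.random.Generator) -> str:
    surname = str(rng.choice(list(_SURNAMES)))
    year = int(rng.integers(1758, 1990))
    if rng.random() < 0.3:
        return f"({surname}, {year})"
    return f"{surname}, {year}"


def generate_authority(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[Authority, dict[str, str]]:
    """Generate the authority bank.

    Returns the authority plus a mapping of accepted canonical name →
    authorship string (the generator's nomenclatural bookkeeping).  Genus
    entries are included as accepted names so uninomial lookups resolve.
    Synonyms are minted by transferring a species to a sibling genus or by
    swapping the gender ending of its epithet, and always point at their
    accepted name, so the closure invariant holds by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    entries: list[AuthorityEntry] = []
    authorships: dict[str, str] = {}
    genera: list[str] = []
    seen: set[str] = set()
    while len(genera) < config.n_genera:
        g = _genus_name(rng)
        if g not in seen:
            seen.add(g)
            genera.append(g)

    species: list[str] = []
    for genus in genera:
        entries.append(
            AuthorityEntry(
                canonical=genus,
                rank=Rank.GENUS,
                status="accepted",
                accepted_canonical=genus,
                source="Synthetic Checklist v1",
                source_url="https://example.org/checklist",
                source_date="2015-04-18",
            )
        )
        used_eps: set[str] = set()
        for _ in range(config.species_per_genus):
            ep = _epithet(rng)
            while ep in used_eps:
                ep = _epithet(rng)
            used_eps.add(ep)
            canonical = f"{genus} {ep}"
            species.append(canonical)
            authorships[canonical] = _authorship(rng)
            entries.append(
                AuthorityEntry(
                    canonical=canonical,
                    rank=Rank.SPECIES,
                    status="accepted",
                    accepted_canonical=canonical,
                    source="Synthetic Checklist v1",
                    source_url="https://example.org/checklist",
                    source_date="2015-04-18",
                )
            )
            if rng.random() < config.subspecies_rate:
                sub = _epithet(rng)
                tri = f"{canonical} {sub}"
                species.append(tri)
                authorships[tri] = _authorship(rng)
                entries.append(
                    AuthorityEntry(
                        canonical=tri,
                        rank=Rank.INFRASPECIFIC,
                        status="accepted",
                        accepted_canonical=tri,
                        source="Synthetic Checklist v1",
                        source_url="https://example.org/checklist",
                        source_date="2015-04-18",
                    )
                )

    existing = {e.canonical for e in entries}
    for canonical in list(species):
        if rng.random() >= config.synonym_rate:
            continue
        tokens = canonical.split()
        if rng.random() < 0.5:
            # genus transfer
            other = str(rng.choice([g for g in genera if g != tokens[0]]))
            syn = " ".join([other] + tokens[1:])
        else:
            # gender-ending swap on the terminal epithet
            terminal = tokens[-1]
            syn = None
            for old, new in _GENDER_SWAPS:
                if terminal.endswith(old):
                    syn = " ".join(tokens[:-1] + [terminal[: -len(old)] + new])
                    break
            if syn is None:
                other = str(rng.choice([g for g in genera if g != tokens[0]]))
                syn = " ".join([other] + tokens[1:])
        if syn in existing:
            continue
        existing.add(syn)
        authorships[syn] = authorships.get(canonical, _authorship(rng))
        entries.append(
            AuthorityEntry(
                canonical=syn,
                rank=Rank.SPECIES if len(tokens) == 2 else Rank.INFRASPECIFIC,
                status="synonym",
                accepted_canonical=canonical,
                source="Synthetic Checklist v1",
                source_url="https://example.org/checklist",
                source_date="2015-04-18",
            )
        )
    return Authority(entries), authorships


_EDIT_OPS = ("insert", "delete", "substitute", "transpose")
_LETTERS = list("abcdefghijklmnopqrstuvwxyz")


def _apply_edit(name: str, rng: np.random.Generator) -> str:
    """One random character edit, confined to lowercase letters so that
    capitalization and tokenization stay intact (those belong to the format
    class)."""
    positions = [i for i, c in enumerate(name) if c.islower()]
    for _ in range(50):
        op = str(rng.choice(_EDIT_OPS))
        if op == "insert":
            i = int(rng.choice(positions))
            out = name[:i] + str(rng.choice(_LETTERS)) + name[i:]
        elif op == "delete":
            cand = [i for i in positions if i > 0 and name[i - 1] != " "
                    and (i + 1 >= len(name) or name[i + 1] != " ")]
            if not cand:
                continue
            i = int(rng.choice(cand))
            out = name[:i] + name[i + 1:]
        elif op == "substitute":
            i = int(rng.choice(positions))
            c = str(rng.choice(_LETTERS))
            if c == name[i]:
                continue
            out = name[:i] + c + name[i + 1:]
        else:  # transpose adjacent
            cand = [i for i in positions
                    if i + 1 in positions and name[i] != name[i + 1]]
            if not cand:
                continue
            i = int(rng.choice(cand))
            out = name[:i] + name[i + 1] + name[i] + name[i + 2:]
        if out != name:
            return out
    return name


def _misspell(
    name: str, k: int, rng: np.random.Generator, forbidden: set[str]
) -> str:
    """Apply edits until the result sits at distance exactly k from ``name``
    and collides with no authority canonical."""
    for _ in range(100):
        out = name
        for _ in range(k):
            out = _apply_edit(out, rng)
        if damerau_levenshtein(out, name) == k and out not in forbidden:
            return out
    raise RuntimeError(f"could not misspell {name!r} at distance {k}")


_QUALIFIER_INJECTIONS = ("sp.", "cf.", "?")


def corrupt_name(
    clean_canonical: str,
    authorship: str,
    issues: Iterable[str],
    authority: Authority,
    rng: np.random.Generator,
    record_id: str = "n1",
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[NameRecord, TruthLabel]:
    """Corrupt one clean name with the requested issue classes.

    The record is populated in one of three provider styles — atomic fields
    only, ``scientificName`` only, or both — sampled per name.  Synonym
    injection replaces the name with a junior synonym from the authority
    (error if none exists); misspelling applies 1–2 random character edits;
    format and conceptual corruptions each pick one concrete sub-kind
    applicable to the record.  The truth label records everything injected.
    """
    issues = frozenset(issues)
    unknown = issues - {"misspelling", "format", "conceptual", "synonym"}
    if unknown:
        raise ValueError(f"unknown issue classes: {sorted(unknown)}")

    name = clean_canonical
    label = TruthLabel(
        id=record_id, clean_canonical=clean_canonical, issues=issues
    )

    if "synonym" in issues:
        synonyms = [
            e.canonical
            for e in authority
            if e.status == "synonym" and e.accepted_canonical == clean_canonical
        ]
        if not synonyms:
            raise ValueError(f"no junior synonym available for {clean_canonical!r}")
        name = str(rng.choice(sorted(synonyms)))
        label = replace(label, synonym_used=name)

    if "misspelling" in issues:
        k = 2 if rng.random() < config.second_edit_rate else 1
        forbidden = {e.canonical for e in authority}
        name = _misspell(name, k, rng, forbidden)
        label = replace(label, n_edits=k)

    tokens = name.split()
    genus = tokens[0] if tokens else ""
    specific = tokens[1] if len(tokens) > 1 else ""
    infra = tokens[2] if len(tokens) > 2 else ""

    style = str(rng.choice(["atomic", "scientificName", "both"]))
    label = replace(label, provider_style=style)

    use_atomic = style in ("atomic", "both")
    use_sn = style in ("scientificName", "both")

    rec = NameRecord(id=record_id)
    if use_atomic:
        rec.genus = genus
        rec.specificEpithet = specific
        rec.infraspecificEpithet = infra
        rec.scientificNameAuthorship = authorship
    if use_sn:
        rec.scientificName = name + (f" {authorship}" if rng.random() < 0.5 else "")

    if "conceptual" in issues:
        kinds = ["qualifier"]
        if use_atomic and specific and authorship:
            kinds.append("autherr")
        if infra and rec.scientificName and infra in rec.scientificName.split():
            kinds.append("binomial_only")
        # the only-infraspecific pattern destroys the genus and species, so
        # it is injected alone — a name reduced to its terminal epithet can
        # no longer witness a synonym swap or a misspelling
        if infra and style == "atomic" and issues == {"conceptual"}:
            kinds.append("only_infraspecific")
        kind = str(rng.choice(kinds))
        if kind == "qualifier":
            q = str(rng.choice(_QUALIFIER_INJECTIONS))
            if rec.scientificName:
                rec.scientificName = f"{rec.scientificName} {q}"
            else:
                rec.infraspecificEpithet = (
                    f"{rec.infraspecificEpithet} {q}".strip()
                    if rec.infraspecificEpithet
                    else q
                )
                if not rec.infraspecificEpithet.strip():
                    rec.specificEpithet = f"{rec.specificEpithet} {q}".strip()
        elif kind == "autherr":
            # displaced authorship trails the terminal epithet, as providers
            # that atomize a label left-to-right produce it
            if infra:
                rec.infraspecificEpithet = f"{infra} {authorship}"
            else:
                rec.specificEpithet = f"{specific} {authorship}"
            rec.scientificNameAuthorship = ""
        elif kind == "binomial_only":
            rec.scientificName = f"{genus} {specific}"
            rec.infraspecificEpithet = infra
            if use_atomic:
                pass
            else:
                rec.genus = ""
        else:  # only_infraspecific
            rec.genus = ""
            rec.specificEpithet = ""
            rec.scientificNameAuthorship = ""
            rec.scientificName = ""
            rec.infraspecificEpithet = infra
        label = replace(label, conceptual_kind=kind)

    if "format" in issues:
        kinds = ["whitespace"]
        if rec.genus or (rec.scientificName and not rec.scientificName[0].islower()):
            kinds.append("genus_lower")
        if rec.specificEpithet or len(rec.scientificName.split()) > 1:
            kinds.append("epithet_cap")
        if rec.scientificNameAuthorship:
            kinds.append("auth_lower")
        # an abbreviated genus is only unambiguously expandable when the rest
        # of the name is intact, so the abbreviation sub-kind is not combined
        # with synonym or misspelling injections
        if rec.genus and not issues & {"synonym", "misspelling"}:
            kinds.append("abbreviation")
        kind = str(rng.choice(kinds))
        if kind == "whitespace":
            if rec.scientificName:
                parts = rec.scientificName.split(" ")
                if len(parts) > 1:
                    rec.scientificName = parts[0] + "  " + " ".join(parts[1:])
                else:
                    rec.scientificName = rec.scientificName + " "
            elif rec.genus:
                rec.genus = " " + rec.genus
            else:
                rec.infraspecificEpithet = rec.infraspecificEpithet + " "
        elif kind == "genus_lower":
            if rec.genus:
                rec.genus = rec.genus[:1].lower() + rec.genus[1:]
            if rec.scientificName:
                rec.scientificName = (
                    rec.scientificName[:1].lower() + rec.scientificName[1:]
                )
        elif kind == "epithet_cap":
            if rec.specificEpithet:
                rec.specificEpithet = (
                    rec.specificEpithet[:1].upper() + rec.specificEpithet[1:]
                )
            if rec.scientificName:
                parts = rec.scientificName.split()
                if len(parts) > 1:
                    parts[1] = parts[1][:1].upper() + parts[1][1:]
                    rec.scientificName = " ".join(parts)
        elif kind == "auth_lower":
            a = rec.scientificNameAuthorship
            stripped = a.lstrip("(")
            prefix = a[: len(a) - len(stripped)]
            rec.scientificNameAuthorship = (
                prefix + stripped[:1].lower() + stripped[1:]
            )
        else:  # abbreviation
            if rec.genus:
                rec.genus = rec.genus[0] + "."
            if rec.scientificName:
                parts = rec.scientificName.split()
                parts[0] = parts[0][0] + "."
                rec.scientificName = " ".join(parts)
        label = replace(label, format_kind=kind)

    return rec, label


def simulate_covariates(
    n: int,
    rng: np.random.Generator,
    config: GeneratorConfig = GeneratorConfig(),
) -> pd.DataFrame:
    """Covariate frame with realistic marginals for n occurrence records.

    Record volumes per institution are log-normal (collections span orders
    of magnitude); regions are dominated by North America, mirroring the
    provenance of aggregated vertebrate collections.
    """
    regions = ("North America", "South America", "Europe", "Asia", "Africa",
               "Australasia", "Oceania")
    region_p = (0.60, 0.10, 0.08, 0.08, 0.06, 0.05, 0.03)
    clades = ("Aves", "Fishes", "Mammalia", "Amphibia", "Reptilia")
    clade_p = (0.36, 0.33, 0.15, 0.08, 0.08)

    inst_codes = [f"INST{i:03d}" for i in range(config.n_institutions)]
    inst_sizes = np.maximum(
        1, np.exp(rng.normal(7.0, 1.5, size=config.n_institutions))
    ).astype(int)
    inst_idx = rng.choice(
        config.n_institutions, size=n, p=inst_sizes / inst_sizes.sum()
    )
    lo, hi = config.year_range
    return pd.DataFrame(
        {
            "basisOfRecord": rng.choice(
                ["PreservedSpecimen", "FossilSpecimen"], size=n, p=[0.9, 0.1]
            ),
            "region": rng.choice(regions, size=n, p=region_p),
            "clade": rng.choice(clades, size=n, p=clade_p),
            "year": rng.integers(lo, hi + 1, size=n),
            "institutionCode": [inst_codes[i] for i in inst_idx],
            "institutionRecords": inst_sizes[inst_idx],
        }
    )


def simulate_issue_outcomes(
    design: pd.DataFrame | np.ndarray,
    coefficients: Sequence[float] | Mapping[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Bernoulli outcomes with p = inverse-logit(X @ beta).

    ``coefficients`` may be a vector conformable with the design columns or
    a mapping from design column name to value (missing columns get 0).
    """
    if isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
        columns = list(design.columns)
    else:
        X = np.asarray(design, dtype=float)
        columns = None
    if isinstance(coefficients, Mapping):
        if columns is None:
            raise ValueError("named coefficients require a DataFrame design")
        beta = np.array([coefficients.get(c, 0.0) for c in columns], dtype=float)
    else:
        beta = np.asarray(coefficients, dtype=float)
    if beta.shape[0] != X.shape[1]:
        raise ValueError(
            f"coefficient vector of length {beta.shape[0]} is not conformable "
            f"with design of width {X.shape[1]}"
        )
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(X.shape[0]) < p).astype(int)


def generate_dataset(config: GeneratorConfig) -> Bundle:
    """End-to-end synthetic bundle: names, occurrences, authority, truth.

    Issue classes are drawn independently per name at the configured rates;
    occurrence counts per name are geometric with the configured mean;
    occurrences inherit the verbatim name fields so the six-field join keys
    match by construction.
    """
    rng = np.random.default_rng(config.seed)
    authority, authorships = generate_authority(config, rng)

    accepted_with_synonym = sorted(
        {
            e.accepted_canonical
            for e in authority
            if e.status == "synonym"
        }
    )
    accepted_species = sorted(
        e.canonical
        for e in authority
        if e.status == "accepted" and e.rank is not Rank.GENUS
    )

    # draw species without replacement so the generated name combinations are
    # distinct and the realized issue rates are unbiased by deduplication
    syn_pool = list(accepted_with_synonym)
    other_pool = sorted(set(accepted_species) - set(accepted_with_synonym))
    rng.shuffle(syn_pool)
    rng.shuffle(other_pool)

    def draw_clean(need_synonym: bool) -> str | None:
        if need_synonym:
            return syn_pool.pop() if syn_pool else None
        if other_pool:
            return other_pool.pop()
        return syn_pool.pop() if syn_pool else None

    names: list[NameRecord] = []
    truth: dict[str, TruthLabel] = {}
    seen_keys: set[tuple] = set()
    for i in range(config.n_names):
        record_id = f"name{i:05d}"
        issues = set()
        if rng.random() < config.rate_misspelling:
            issues.add("misspelling")
        if rng.random() < config.rate_format:
            issues.add("format")
        if rng.random() < config.rate_conceptual:
            issues.add("conceptual")
        if rng.random() < config.rate_synonym:
            issues.add("synonym")
        clean = draw_clean("synonym" in issues)
        if clean is None and "synonym" in issues:
            issues.discard("synonym")
            clean = draw_clean(False)
        if clean is None:
            clean = str(rng.choice(accepted_species))
        rec, label = corrupt_name(
            clean,
            authorships.get(clean, ""),
            issues,
            authority,
            rng,
            record_id=record_id,
            config=config,
        )
        key = (rec.scientificName, rec.genus, rec.subgenus, rec.specificEpithet,
               rec.infraspecificEpithet, rec.scientificNameAuthorship)
        if key in seen_keys:
            continue  # keep combinations distinct, as in real vetting sets
        seen_keys.add(key)
        names.append(rec)
        truth[record_id] = label

    occurrences: list[OccurrenceRecord] = []
    if config.mean_occurrences_per_name > 0 and names:
        counts = rng.geometric(
            1.0 / config.mean_occurrences_per_name, size=len(names)
        )
        total = int(counts.sum())
        cov = simulate_covariates(total, rng, config)
        region_to_country = {
            "North America": "United States",
            "South America": "Brazil",
            "Europe": "France",
            "Asia": "Japan",
            "Africa": "Kenya",
            "Australasia": "Australia",
            "Oceania": "Fiji",
        }
        clade_to_class = {
            "Aves": "Aves",
            "Mammalia": "Mammalia",
            "Amphibia": "Amphibia",
            "Reptilia": "Reptilia",
            "Fishes": "Actinopterygii",
        }
        j = 0
        for rec, c in zip(names, counts):
            for _ in range(int(c)):
                row = cov.iloc[j]
                occurrences.append(
                    OccurrenceRecord(
                        occurrence_id=f"occ{j:06d}",
                        scientificName=rec.scientificName,
                        genus=rec.genus,
                        subgenus=rec.subgenus,
                        specificEpithet=rec.specificEpithet,
                        infraspecificEpithet=rec.infraspecificEpithet,
                        scientificNameAuthorship=rec.scientificNameAuthorship,
                        basisOfRecord=str(row["basisOfRecord"]),
                        country=region_to_country[str(row["region"])],
                        continent=str(row["region"]),
                        year=str(int(row["year"])),
                        class_=clade_to_class[str(row["clade"])],
                        institutionCode=str(row["institutionCode"]),
                        extras={"datasetName": f"ds-{row['institutionCode']}"},
                    )
                )
                j += 1

    return Bundle(
        names=names,
        occurrences=occurrences,
        authority=authority,
        truth=truth,
        config=config,
    )
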