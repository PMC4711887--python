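# Methods

## The assessment model

A *name combination* is a distinct tuple of the six verbatim Darwin Core
taxon fields.  The package treats vetting as a deterministic pipeline over
such tuples: assemble convenience strings, detect issues, resolve against an
authority, roll up, and (optionally) link to occurrence records and model
issue drivers.  Verbatim content is never modified; every normalization is
an explicit, flagged operation whose output lives in derived fields.

### Convenience strings and ranks

`constructedscientificname` is the space-separated concatenation of `genus`,
`subgenus`, `specificEpithet`, `infraspecificEpithet` and
`scientificNameAuthorship`, skipping empty fields.  When only the
infraspecific epithet is populated the constructed name is left blank: that
field pattern signals a provider convention in which `scientificName` holds
the full name and only the terminal epithet is atomized, and a bare epithet
is not a resolvable name.  `scientificnameplus` appends the infraspecific
epithet to `scientificName` when both are populated and the epithet is not
already a whole token of the name.  The containment test is case-sensitive
whole-token membership: a substring test would wrongly suppress epithets
that prefix longer tokens (`alba` in `albana`).

Rank inference strips authorship-like tokens and counts what remains: one
capitalized token is a genus, two tokens a species, three or more an
infraspecific name; a parenthesized (or, in the constructed string, bare
capitalized) second token followed by epithets is a subgenus.  A token is
authorship-like if it is a four-digit year, starts with `(`, contains a
comma, or is a capitalized token after at least two lowercase epithets.
This heuristic is deliberately conservative: names it cannot classify are
ranked *indeterminate* rather than guessed, so misparses surface as flags,
never as silent corruption.  It does not attempt full nomenclatural parsing
(basionym authorship, `ex` authors, `sensu` qualifiers are out of scope).

### Issue classes and detectors

Four classes are assessed, with `hasIssue` true when any is present and
`hasError` covering the first three (synonymy is an issue, not an error):

- **Format errors** — leading/trailing/doubled whitespace in any field,
  uncapitalized genus, capitalized epithet, authorship whose surnames are
  not capitalized (`con-authcap`), and abbreviations (single-letter genus
  with a period).  In `scientificName` any bare capitalized token in epithet
  position counts as a capitalization error; the subgenus reading is
  reserved for parenthesized tokens, since that is the convention in that
  field.
- **Darwin Core conceptual errors** — identification qualifiers inside name
  fields (`sp.`, `spp.`, `ssp.`, `cf.`, `aff.`, `nr.`, `?`, and a trailing
  bare `sp`; the first three and `?` are the canonical offenders, the rest
  conservative extensions, each removable via `DetectionConfig`); authorship
  content inside an epithet field (`con-autherr`); a binomial-only
  `scientificName` next to a populated infraspecific epithet
  (`sn-inf-missing`); only the infraspecific epithet populated; malformed
  subgenus content (`con-sgerror`); and a constructed name whose
  case-normalized rank is indeterminate (`con-rnk`).  The precise definitions
  of `sn-inf-missing`, `con-sgerror` and `con-rnk` are provisional: they are
  named after assessment fields whose full definitions are not published,
  and our operationalizations are documented here and versioned with the
  code.
- **Misspellings** — charged exclusively by resolution: a name that reaches
  the authority only through a fuzzy match at edit distance ≥ 1.
- **Synonymy** — tri-state (`yes`/`no`/`indeterminate`): a name resolving to
  an entry with synonym status is a synonym; a name that cannot be resolved
  at all is indeterminate, because absence from the authority proves
  nothing either way.  Indeterminate records are retained in outputs but
  excluded from driver modelling.

A constructed name containing only well-formed authorship is not treated as
invalid; only malformed authorship (wrong capitalization, bad dates) raises
a flag.

### Resolution

Both convenience strings are candidates.  Each is reduced to a canonical
core — authorship and qualifier tokens dropped, whitespace collapsed, genus
capitalized and epithets lowercased — and tried against the authority:

1. exact accepted hit: valid as-is;
2. exact synonym hit: `isSynonym = yes`, valid name is the stored accepted
   name (the authority stores terminal accepted names, so chains resolve in
   one hop, and resolution is idempotent);
3. abbreviated-genus expansion (`P. major`): entries sharing the genus
   initial whose remaining tokens match exactly or within the fuzzy radius;
4. fuzzy lookup: all entries within the radius, ordered by distance, then
   accepted-before-synonym, then lexicographically.  A fuzzy hit charges
   `hasMisspelling`; a fuzzy hit on a synonym entry charges both flags
   (misspelled junior synonyms need multi-stage cleaning, and the comment
   records it).

The fuzzy radius defaults to 1 edit for uninomials, 2 for binomials, 3 for
trinomials — wide enough for the realistic corruption classes (gender
endings are 1–2 edits) while bounding false matches; all three are
configurable, and no published numeric threshold exists for the manual
process these defaults emulate.  Distance is computed on the full
case-normalized string rather than per token, matching the description of
misspellings as whole-string character edits; capitalization problems are
charged to the format detector, never to the distance.  When the two
candidates disagree, the one reaching an accepted name with fewer
corrections wins, with the constructed (atomic-field) candidate preferred on
ties because atomic fields are closer to the source of truth; every
disagreement and every ambiguous tie is logged in `comments`, so callers can
treat ties as indeterminate if they prefer.  Deterministic tie-breaking was
chosen over failure-on-ambiguity so that batch runs are reproducible.

### Edit distance

The unrestricted Damerau–Levenshtein distance (Lowrance–Wagner algorithm)
with unit-cost insertions, deletions, substitutions and transpositions.
The common restricted variant ("optimal string alignment") was rejected
because it violates the triangle inequality; the unrestricted form is a true
metric, which the property tests assert.  An optional SIMD Levenshtein
prefilter (edlib) accelerates fuzzy scans using the bound
`Levenshtein ≤ 2 × Damerau–Levenshtein`; results are identical with or
without it.

### Linking and covariates

Names join to occurrences on a key concatenating the six verbatim fields
with the ASCII unit separator — a non-printing character that real data
never contains, making key collisions impossible.  The join is exact inner
join semantics on verbatim bytes, duplicates each counted.

For modelling, `basisOfRecord` is normalized (case- and
separator-insensitively) to the Darwin Core recommended vocabulary and only
`FossilSpecimen` and `PreservedSpecimen` records are retained; region is
derived from country (via a bundled, editable mapping table covering common
country names) or continent into seven regions (Africa, Asia, Australasia,
Europe, North America, Oceania, South America), with Antarctica excluded;
the taxonomic class collapses to five clades, "Fishes" grouping
Actinopterygii, Cephalaspidomorphi, Conodonta, Elasmobranchii, Holocephali,
Myxini, Placodermi and Sarcopterygii; years must be plausible 4-digit
collection years (1700–2100 by default; ranges and partial dates are
excluded).  Records failing a step are excluded with exactly one primary
reason, applied in the fixed order basisOfRecord → region → year → clade.
The bundled country table is a documented substitute for a full gazetteer;
marine localities without a country fall out as region exclusions.
Institutional record counts default to in-table tallies per
`institutionCode`; pass an external mapping when a network-wide census is
available.

### Summaries and effort

The summary table reports, per category, name-combination and
matching-occurrence counts with percentages at one decimal (half-up
rounding, stored at one decimal even when a trailing zero would be
suppressed in display), plus distinct institutions and data sets from the
matched occurrence set.  Data-set counts use a pass-through `datasetName`
column when the occurrence table carries one, else 0 — the occurrence schema
itself has no data-set field.  Indeterminate synonymy is its own row and is
excluded from the Synonym count.  Dual-resolution records (ids passed as
exclusions) are dropped from every row except the first three, which always
describe the full assessed set.  The overlap table partitions issue-bearing
combinations into the 15 non-empty subsets of the four classes; its
marginals equal the per-class summary counts by construction, and both are
asserted on every run.

Effort projection is a straight proportional scale-up of the manual vetting
rate — defaults 4 hours per 100 records, about 2 minutes per record —
rounded half-up to whole person-hours.

## Driver models

Binomial GLM with logit link (maximum likelihood via IRLS, statsmodels).
Categorical covariates use treatment coding with reference levels
PreservedSpecimen, North America and Aves (configurable; no published
contrasts exist to copy).  Year enters centered and scaled; institutional
record count enters as `standardize(log(count))` — record volumes span
orders of magnitude, and the log keeps the largest collections from
dominating the linear predictor; both transforms are stateful in-formula
operations, so effect profiles accept grids on the original scale.
Whether to bin the count was an open choice; it is kept continuous.

Model search enumerates all subsets of the C(5,2) = 10 pairwise
interactions — 1,024 fits — and ranks by AIC with ΔAIC against the best.
The enumeration is capped at 2^10; for larger covariate sets the search is
deliberately out of scope rather than silently greedy.  A member that fails
to fit is flagged with its error and ranked last, never dropped.
Non-convergence and separation (unstable standard errors) raise structured
errors naming the offending terms.  Per-issue models are main-effects only:
with interactions present in the overall model, per-issue comparisons on
main effects are the interpretable contrast.

Pseudo-R²: McFadden `1 − ll₁/ll₀`; Nagelkerke as the Cox–Snell ratio
rescaled by its attainable maximum.  Both are recomputed from raw
log-likelihood arithmetic in the tests (including a 20-row fixture whose
group-wise MLE has closed form).  The AIC identity
`AIC = −2·logLik + 2·parameters` is asserted independently.

Effect profiles hold non-focal covariates at their reference level
(categorical) or mean (continuous) and report inverse-logit predictions
with delta-method confidence bands; grid points outside the observed range
are annotated, not rejected.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
full determinism under a seed:

- **Authority bank** — pronounceable latinized names from syllable
  templates (150 genera × 6 species, 15% subspecies by default; no real
  taxon names).  Junior synonyms (30% of species) are minted by genus
  transfer or epithet gender-ending swap and always point at their accepted
  name, so the closure invariant holds by construction.
- **Name combinations** — issue classes combine independently per name at
  the prevalences observed in vetted aggregator data (misspelling 12.9%,
  format 8.9%, conceptual 13.7%, synonymy 27%), which exercises all fifteen
  overlap cells.  Species are drawn without replacement so combinations are
  distinct and realized rates are unbiased.  Each record is populated in one
  of three provider styles (atomic fields only, `scientificName` only, or
  both).  Misspellings apply one edit (70%) or two (30%), confined to
  lowercase letters so capitalization and tokenization stay with the format
  class, and are re-rolled if they collide with another authority entry.
  Two sub-kind gates keep injected truth recoverable: the only-infraspecific
  pattern is injected alone (a name reduced to its epithet cannot witness a
  synonym or misspelling), and genus abbreviation is not combined with
  synonym or misspelling (an abbreviated corrupted name is not
  unambiguously expandable).  These gates are mild dependence between
  classes and sub-kinds, not between the four classes themselves.
- **Occurrences** — per-name counts are geometric with mean 27 (matching
  the observed ratio of occurrences to distinct names in aggregated
  vertebrate data); covariates use realistic marginals: 90%
  PreservedSpecimen, regions dominated by North America (60%), clade mix
  led by birds and fishes, years uniform over 1900–2015, and log-normal
  institutional record volumes over 40 institutions.  Binary issue outcomes
  can be drawn from any logit model over the design matrix, enabling
  coefficient-recovery experiments against known truth.

What the generator does *not* emulate: real provider heterogeneity and
correlated field corruption, taxonomically real names, the paper trail of
human vetting disagreements, or occurrence-level dependence of issues on
covariates in the default bundle (name-level issue draws are independent of
the occurrence covariates unless outcomes are explicitly simulated from a
logit model).  Passing detector-recall tests therefore demonstrates that the
detectors recover the corruption classes they define, at realistic rates, on
clean-room data — not that real aggregator data contains no further failure
modes.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 1,000-name bundles for
detector fidelity; 50 replicates at n = 20,000 for coefficient coverage and
for interaction recovery (the latter over 3 covariates, 8 candidate models
per replicate, with the full 5-covariate enumeration verified as a count);
10,000 random pairs for the edit-distance oracle; and a 10³ × 10³ instance
for the join oracle.  These sizes give stable statistics in minutes on one
CPU.

Percentages use decimal half-up rounding at one decimal; effort projection
half-up to whole hours.  Fuzzy ties and candidate disagreements break
deterministically and are logged.  Empty inputs: a zero-name bundle is valid
and empty; an empty assessment collection is a structured error in
summaries; a constant response is a structured error in model fitting.

## Known limitations

- The authority is single-voice: multi-source conflict arbitration (choosing
  among disagreeing checklists) is out of scope, as is live querying of
  online aggregators.
- Identification errors (wrong determinations, detectable only against
  range maps and expert review) are out of scope by design.
- Rank inference and authorship stripping are heuristics; unusual authorship
  (no comma before the year, lowercase particles beyond the built-in list)
  can leave a name indeterminate rather than resolved.
- The gold/silver/bronze vetting-depth attribute (`checked`) is carried as
  data but no multi-vetter workflow is implemented.
- Misspelled junior synonyms resolve deterministically to the nearest entry;
  when a gender-swapped synonym and its accepted name are equidistant the
  accepted name wins and the ambiguity is logged, so such cases count as
  misspellings, not synonymy.
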