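# taxonvet

Quality assessment and resolution of scientific names in digitized
biocollections data.

Taxon names attached to museum specimen records — the Darwin Core fields
`scientificName`, `genus`, `subgenus`, `specificEpithet`,
`infraspecificEpithet` and `scientificNameAuthorship` — are frequently
misspelled, formatted inconsistently, mapped to the wrong field, or simply
out of date.  Before occurrence records can be used in biodiversity research
these problems have to be found and fixed.  `taxonvet` implements a complete,
reproducible version of that vetting workflow for data managers and
biodiversity informaticians:

- **assemble** two convenience strings per name combination — a
  `constructedscientificname` concatenated from the atomic fields and a
  `scientificnameplus` that restores an infraspecific epithet missing from
  `scientificName` — and infer the taxon rank of each;
- **detect and classify** four issue classes per combination: *misspellings*
  (character insertions, deletions, substitutions, transpositions),
  *format errors* (mis-capitalization, extra whitespace, abbreviations),
  *Darwin Core conceptual errors* (identification qualifiers such as
  `sp.`/`cf.`/`?` inside name fields, authorship in an epithet field,
  binomial-only `scientificName` next to a populated epithet), and
  *synonymy* (a junior synonym of a currently accepted name — an issue but
  not an error);
- **resolve** each combination to a valid canonical name against a local,
  pluggable taxonomic authority using exact lookup, transposition-aware
  (Damerau–Levenshtein) fuzzy matching, abbreviation expansion and one-hop
  synonym chasing;
- **link** assessments back to occurrence records through an inner join on
  the six verbatim fields, and **summarize** issue prevalence and overlap;
- **model** the drivers of issues with logistic regression over five
  standardized covariates (record type, geographic region, clade, collection
  year, institutional record volume), including exhaustive AIC ranking of
  all 2^10 two-way-interaction subsets and McFadden/Nagelkerke pseudo-R²;
- **simulate** full data sets with known ground truth — authority banks,
  issue-injected name combinations, occurrence tables with covariates and
  logit-model outcomes — so every detector and model can be validated
  against injected truth.

## Worked example

Assess one messy name combination — a lowercased genus, doubled whitespace,
and a misspelled junior synonym — against a three-entry authority:

```python
from taxonvet import Authority, AuthorityEntry, NameRecord, Rank, assess_record

authority = Authority([
    AuthorityEntry("Cyanistes", Rank.GENUS, "accepted", "Cyanistes"),
    AuthorityEntry("Cyanistes caeruleus", Rank.SPECIES, "accepted",
                   "Cyanistes caeruleus", source="Birds Checklist 2015"),
    AuthorityEntry("Parus caeruleus", Rank.SPECIES, "synonym",
                   "Cyanistes caeruleus", source="Birds Checklist 2015"),
])
record = NameRecord(id="ex1", scientificName="Parus  caerulues",
                    genus="parus", specificEpithet="caerulues",
                    scientificNameAuthorship="Linnaeus, 1758")
assessment = assess_record(record, authority)
```

The assessment prints:

```
hasMisspelling: True
hasFormatError: True
hasConceptualError: False
isSynonym: yes
hasIssue: True
hasError: True
validCanonical: Cyanistes caeruleus
validSource: Birds Checklist 2015
comments: misspelled junior synonym: corrected then resolved
```

`caerulues` is one transposition away from the junior synonym
`Parus caeruleus`, which resolves in one hop to the accepted
`Cyanistes caeruleus`; the whitespace and capitalization problems are charged
to the format class, not to the edit distance.  Scaling up, projecting the
manual vetting rate of 4 hours per 100 records to a 522,163-name corpus:

```python
from taxonvet import project_effort
project_effort(522163, 4.0, 100)   # -> 20887 person-hours
```

## Command line

```bash
taxonvet simulate --seed 1 --n-names 1000 --out bundle/
taxonvet run --names bundle/names.tsv --authority bundle/authority.tsv \
             --occurrences bundle/occurrences.tsv --out results/
```

`run` writes the assessment table, prevalence summary, issue-overlap table
and a provenance manifest (input hashes, config, version).  Each stage is
also available as its own command (`assess`, `link`, `summarize`, `model`).
Exit codes: 0 success, 2 validation error, 3 stage failure.

## Statistical models

`IssueDriverModel.from_dataframe(df, response="hasIssue").fit()` fits a
binomial GLM with logit link and returns an `IssueDriverResults` with
coefficient table, AIC (`−2·logLik + 2·parameters`), both pseudo-R² measures

- McFadden: `1 − logLik(model)/logLik(null)`
- Nagelkerke: `[1 − exp((2/n)(ll₀ − ll₁))] / [1 − exp((2/n)·ll₀)]`

and delta-method effect profiles.  `select_model_aic` enumerates every
subset of the pairwise covariate interactions and ranks the fits by AIC.
Records with indeterminate synonymy are excluded from modelling.

## Documentation

`docs/methods.md` describes the assessment model, the detector rules and
their provisional parts, the synthetic-data generator and what passing tests
do and do not demonstrate about real aggregator data, and the numerical
choices (tie-breaking, rounding, reference levels) in detail.
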